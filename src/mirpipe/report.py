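"""Render integrated miRNA-mRNA pair results as TSV and static HTML.

The TSV carries every pair field, sorted by the chosen key; the HTML report
is a single self-contained file (inline CSS, embedded data, no timestamps)
with one pre-sorted master table plus per-miRNA and per-target views.
Re-rendering identical input is byte-identical.
"""

from __future__ import annotations

import html
from pathlib import Path

import pandas as pd

from .errors import ValidationError

SORT_KEYS = ("correlation", "evidence", "fold_change")


def _sorted_pairs(pairs: pd.DataFrame, sort_key: str) -> pd.DataFrame:
    tie = ["mirna_id", "target_transcript_id"]
    if sort_key == "correlation":
        return pairs.sort_values(["r"] + tie, kind="mergesort")
    if sort_key == "evidence":
        df = pairs.copy()
        df["_n_sources"] = [
            len([s for s in str(x).split(",") if s]) for x in df["evidence_sources"]
        ] if "evidence_sources" in df.columns else 0
        nval = df["n_validated"] if "n_validated" in df.columns else 0
        df["_evidence"] = df["_n_sources"] + nval
        out = df.sort_values(
            ["_evidence"] + tie, ascending=[False, True, True], kind="mergesort"
        )
        return out.drop(columns=["_n_sources", "_evidence"])
    if sort_key == "fold_change":
        df = pairs.copy()
        df["_absfc"] = df["mrna_log2fc"].abs()
        out = df.sort_values(
            ["_absfc"] + tie, ascending=[False, True, True], kind="mergesort"
        )
        return out.drop(columns=["_absfc"])
    raise ValidationError(f"unknown sort key {sort_key!r}; choose from {SORT_KEYS}")


def _html_table(df: pd.DataFrame) -> str:
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in df.columns)
    rows = []
    for _, row in df.iterrows():
        cells = "".join(
            "<td>{}</td>".format(
                html.escape(f"{v:.4g}" if isinstance(v, float) else str(v))
            )
            for v in row
        )
        rows.append(f"<tr>{cells}</tr>")
    return (
        f"<table><thead><tr>{head}</tr></thead><tbody>"
        + "".join(rows)
        + "</tbody></table>"
    )


_CSS = (
    "body{font-family:sans-serif;margin:2em}"
    "table{border-collapse:collapse;margin:1em 0}"
    "th,td{border:1px solid #999;padding:2px 8px;text-align:left}"
    "th{background:#eee}h2{margin-top:2em}"
)


def write_report(
    pairs: pd.DataFrame,
    sort_key: str = "correlation",
    formats: set[str] = frozenset({"tsv"}),
    out_dir: str | Path = ".",
) -> list[Path]:
    """Write the pair report in the requested formats; returns written paths.

    Sort keys: ``correlation`` (r ascending), ``evidence`` (supporting
    source count + validated count, descending), ``fold_change``
    (|mRNA log2FC| descending). Ties break on (mirna_id, target id).
    """
    bad = set(formats) - {"tsv", "html"}
    if bad:
        raise ValidationError(f"unknown format(s): {sorted(bad)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = _sorted_pairs(pairs, sort_key)
    written: list[Path] = []
    if "tsv" in formats:
        tsv_path = out_dir / "pairs.tsv"
        ordered.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
        written.append(tsv_path)
    if "html" in formats:
        if ordered.empty:
            raise ValidationError("cannot render an HTML report for zero pairs")
        parts = [
            "<!DOCTYPE html><html><head><meta charset='utf-8'>",
            f"<title>miRNA-mRNA pair report</title><style>{_CSS}</style></head><body>",
            f"<h1>miRNA-mRNA pair report</h1>",
            f"<p>{len(ordered)} pairs, sorted by {html.escape(sort_key)}.</p>",
            _html_table(ordered),
            "<h2>By miRNA</h2>",
        ]
        for mid, sub in ordered.groupby("mirna_id", sort=True):
            parts.append(f"<h3>{html.escape(str(mid))}</h3>")
            parts.append(_html_table(sub))
        parts.append("<h2>By target</h2>")
        for tid, sub in ordered.groupby("target_transcript_id", sort=True):
            parts.append(f"<h3>{html.escape(str(tid))}</h3>")
            parts.append(_html_table(sub))
        parts.append("</body></html>")
        html_path = out_dir / "pairs.html"
        html_path.write_text("\n".join(parts))
        written.append(html_path)
    return written
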