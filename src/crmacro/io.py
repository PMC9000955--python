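"""Readers and writers for abundance tables, taxonomy, and configuration.

The native table dialect is plain TSV with taxa as rows and sampling times
as columns; the first column holds taxon identifiers. Counts are converted
to per-column relative abundances on read. Taxonomy tables map feature
identifiers (OTU/ASV ids) to ranked lineages so features can be aggregated
to a target rank (the family level is the usual coarse graining of
metabolic capability).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import EnsembleParams
from .simulate import AbundanceTimeSeries

__all__ = [
    "RANKS",
    "read_abundance_table",
    "write_abundance_table",
    "read_taxonomy",
    "aggregate_taxonomy",
    "estimate_N",
    "load_config",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(
    path: str | Path,
    dialect: str | None = None,
    detect: float = 1e-4,
    tol: float = 1e-6,
) -> AbundanceTimeSeries:
    """Read a taxa x times table of counts or relative abundances.

    Counts are converted to per-column relative abundances; columns must
    sum to 1 within ``tol`` after conversion. Sampling times are treated as
    equally spaced.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"cannot parse abundance table {path}: {exc}") from exc
    if frame.empty:
        raise ValueError(f"empty abundance table: {path}")
    if list(frame.columns[:2]) == ["time", "abundance"] and frame.shape[1] == 2:
        # long-format shim: taxon, time, abundance -> wide taxa x times
        frame = frame.reset_index().pivot_table(
            index=frame.index.name or "taxon", columns="time",
            values="abundance", fill_value=0.0,
        )
    values = frame.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("abundance table contains non-finite values")
    if np.any(values < 0):
        raise ValueError("abundance table contains negative values")
    sums = values.sum(axis=0)
    if np.any(sums == 0):
        t = int(np.argmax(sums == 0))
        raise ValueError(f"empty sample: column {frame.columns[t]!r} sums to 0")
    values = values / sums
    if np.any(np.abs(values.sum(axis=0) - 1.0) > tol):
        raise ValueError("columns do not normalize to 1 within tolerance")
    return AbundanceTimeSeries(
        x=values, detect=detect, taxa_ids=[str(i) for i in frame.index],
        meta={"source": str(path), "normalized": True},
    )


def write_abundance_table(
    series: AbundanceTimeSeries, path: str | Path, dialect: str | None = None
) -> None:
    """Write a series as a taxa x times table (lossless round trip)."""
    path = Path(path)
    series.to_frame().to_csv(
        path, sep=_sep_for(path, dialect), float_format="%.17g"
    )


def write_histogram(values, path: str | Path, bins: int = 50) -> None:
    """Export a histogram of pooled values as TSV (value, count)."""
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pd.DataFrame({"value": centers, "count": counts}).to_csv(
        Path(path), sep="\t", index=False
    )


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a two-column TSV of feature id -> semicolon-joined lineage.

    Lineage strings list ranks in the order kingdom;phylum;class;order;
    family;genus; trailing ranks may be omitted.
    """
    table = pd.read_csv(Path(path), sep="\t", header=0, dtype=str)
    if table.shape[1] < 2:
        raise ValueError("taxonomy table needs feature-id and lineage columns")
    out: dict[str, dict[str, str]] = {}
    for _, row in table.iterrows():
        parts = [p.strip() for p in str(row.iloc[1]).split(";")]
        out[str(row.iloc[0])] = {
            rank: parts[i] if i < len(parts) and parts[i] else ""
            for i, rank in enumerate(RANKS)
        }
    return out


def aggregate_taxonomy(
    series: AbundanceTimeSeries,
    taxonomy: dict[str, dict[str, str]],
    rank: str,
    unclassified: str = "pool",
) -> AbundanceTimeSeries:
    """Sum feature abundances within each lineage at the target rank.

    Features lacking an assignment at ``rank`` go to a single
    "unclassified" row (``unclassified='pool'``, default) or are dropped
    (``'drop'``). Column sums are preserved exactly when pooling.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if unclassified not in ("pool", "drop"):
        raise ValueError("unclassified must be 'pool' or 'drop'")
    groups: dict[str, np.ndarray] = {}
    for i, fid in enumerate(series.taxa_ids):
        name = taxonomy.get(fid, {}).get(rank, "")
        if not name:
            if unclassified == "drop":
                continue
            name = "unclassified"
        if name in groups:
            groups[name] = groups[name] + series.x[i]
        else:
            groups[name] = series.x[i].copy()
    if not groups:
        raise ValueError("no features left after aggregation")
    names = sorted(groups)
    return AbundanceTimeSeries(
        x=np.vstack([groups[n] for n in names]),
        detect=series.detect,
        taxa_ids=names,
        meta={**series.meta, "rank": rank},
    )


def estimate_N(series: AbundanceTimeSeries) -> int:
    """Reservoir size estimate: taxa present at >= 1 sampling time."""
    return int(series.present.any(axis=1).sum())


def load_config(path: str | Path) -> EnsembleParams:
    """Load ensemble parameters from a flat YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    return EnsembleParams.from_dict(raw)
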