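"""Tabular I/O: long-format metabolite tables and ASV count tables.

Canonical interchange is plain TSV (comma/tab dialects auto-detected);
sparse counts may be supplied as a matrix-market triplet with row/column name
files.  All readers validate schemas and report offending rows rather than
silently dropping data.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import CountTable
from .fitting import TimeSeriesPair

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "pairs_from_frame",
    "read_counts",
    "write_counts",
    "file_sha256",
]

TS_COLUMNS = ["soil_id", "perturbed_pH", "treatment", "replicate", "time", "nitrate"]


class SchemaError(ValueError):
    pass


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def pairs_from_frame(df: pd.DataFrame) -> tuple[list[TimeSeriesPair], list[tuple]]:
    """Pair chl-/chl+ series by (soil_id, perturbed_pH, replicate).

    Returns the complete pairs and the keys of unpaired arms (excluded with a
    warning).
    """
    missing = [c for c in TS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    pairs, unpaired = [], []
    for key, grp in df.groupby(["soil_id", "perturbed_pH", "replicate"], sort=True):
        arms = {}
        for trt, sub in grp.groupby("treatment"):
            sub = sub.sort_values("time")
            t = sub["time"].to_numpy(float)
            if np.any(np.diff(t) < 0):
                raise SchemaError(f"{key}/{trt}: unsorted times")
            arms[trt] = (t, sub["nitrate"].to_numpy(float))
        if "chl-" in arms and "chl+" in arms:
            pairs.append(TimeSeriesPair(str(key[0]), float(key[1]), int(key[2]),
                                        *arms["chl-"], *arms["chl+"]))
        else:
            unpaired.append(key)
    if unpaired:
        warnings.warn(f"{len(unpaired)} unpaired condition(s) excluded from fitting")
    return pairs, unpaired


def read_timeseries(path) -> tuple[list[TimeSeriesPair], list[tuple]]:
    """Load a long-format metabolite table and pair the treatment arms."""
    return pairs_from_frame(_read_table(path))


def write_timeseries(pairs: list[TimeSeriesPair], path) -> None:
    rows = []
    for p in pairs:
        for trt, t, a in (("chl-", p.t_minus, p.a_minus), ("chl+", p.t_plus, p.a_plus)):
            for ti, ai in zip(t, a):
                rows.append((p.soil_id, p.perturbed_ph, trt, p.replicate, ti, ai))
    pd.DataFrame(rows, columns=TS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts(counts_path, taxonomy_path, meta_path,
                spike_ids: tuple[str, str]) -> CountTable:
    """Load counts (TSV samples x ASVs, or .mtx triplet with ``<stem>.rows``
    and ``<stem>.cols`` name files), taxonomy and metadata TSVs."""
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(counts_path).toarray()
        rows = Path(str(counts_path.with_suffix("")) + ".rows").read_text().split()
        cols = Path(str(counts_path.with_suffix("")) + ".cols").read_text().split()
        counts = pd.DataFrame(mat.astype(int), index=rows, columns=cols)
    else:
        counts = _read_table(counts_path).set_index("sample_id")
    taxonomy = _read_table(taxonomy_path).set_index("asv_id")
    meta = _read_table(meta_path).set_index("sample_id")
    for s in spike_ids:
        if s not in counts.columns:
            raise SchemaError(f"expected spike-in ASV {s!r} not found in counts")
    missing_tax = counts.columns.difference(taxonomy.index).difference(spike_ids)
    if len(missing_tax) > 20:
        raise SchemaError(f"{len(missing_tax)} ASVs lack taxonomy entries, e.g. "
                          f"{list(missing_tax[:5])}")
    missing_meta = counts.index.difference(meta.index)
    if len(missing_meta):
        raise SchemaError(f"samples missing metadata: {list(missing_meta[:5])}")
    return CountTable(counts=counts, taxonomy=taxonomy, meta=meta, spike_ids=spike_ids)


def write_counts(table: CountTable, counts_path, taxonomy_path, meta_path) -> None:
    table.counts.rename_axis("sample_id").to_csv(counts_path, sep="\t")
    table.taxonomy.rename_axis("asv_id").to_csv(taxonomy_path, sep="\t")
    table.meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")
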