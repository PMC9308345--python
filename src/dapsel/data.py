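"""Core containers and tabular I/O for protein log-intensity data.

The central object is a features x samples grid of log-scale intensities
together with per-sample metadata (group label, genotype, treatment,
replicate/batch index).  Group comparisons are binary: the first-listed
group of a comparison is coded y = 1, so a positive effect downstream
always means "higher abundance in the first-listed group".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dapsel")

#: canonical group labels of the 2x2 genotype x treatment design
STANDARD_GROUPS = ("RCK", "MCK", "R400", "M400")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample: group, factorial coordinates, batch index."""

    sample_id: str
    group: str
    genotype: str
    treatment: str
    replicate: int


class IntensityMatrix:
    """Features x samples log-intensity grid with aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id,
        column order matching ``samples``.
    samples
        Sample metadata, one entry per column of ``values``.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta]):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in metadata")
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if list(values.columns) != ids:
            raise ValueError("matrix columns do not match sample metadata order")
        pairs = [(s.group, s.replicate) for s in samples]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(group, replicate) pairs are not unique")
        self.values = values.astype(float)
        self.samples = samples

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "genotype": [s.genotype for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def samples_in_group(self, group: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == group]


class AdjustedMatrix(IntensityMatrix):
    """Batch-corrected matrix; carries a reference to the model fit used."""

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta], provenance=None):
        super().__init__(values, samples)
        self.provenance = provenance


@dataclass(frozen=True)
class Comparison:
    """A binary two-group contrast; ``group_a`` samples are coded y = 1."""

    name: str
    group_a: str
    group_b: str
    axis: str = "group"

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ValueError("comparison groups must differ")

    def subset(self, data: IntensityMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (X, y, feature_ids) for this contrast.

        X is samples x features (float), y is the 0/1 indicator with 1 for
        ``group_a``.  Sample order follows the metadata order of ``data``.
        """
        keep = [s for s in data.samples if s.group in (self.group_a, self.group_b)]
        if not keep:
            raise ValueError(f"no samples found for comparison {self.name}")
        cols = [s.sample_id for s in keep]
        y = np.array([1.0 if s.group == self.group_a else 0.0 for s in keep])
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError(f"comparison {self.name} is missing one of its groups")
        X = data.values[cols].to_numpy().T
        return X, y, data.feature_ids


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_intensity_table(
    matrix_path: str | Path,
    meta_path: str | Path,
    log_transform: bool = False,
) -> IntensityMatrix:
    """Read an intensity matrix (TSV/CSV, feature ids in the first column,
    sample ids in the header) and its sample-metadata CSV.

    Features containing any missing value are dropped (with a logged count);
    ``log_transform`` applies the natural log to positive raw intensities.
    """
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    values = pd.read_csv(
        matrix_path, sep=_sep_for(matrix_path), index_col=0,
        float_precision="round_trip",
    )
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path))
    required = {"sample_id", "genotype", "treatment", "replicate"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if "group" not in meta.columns:
        meta["group"] = meta["genotype"].astype(str) + meta["treatment"].astype(str)

    matrix_ids = set(values.columns)
    meta_ids = set(meta["sample_id"])
    if matrix_ids != meta_ids:
        missing = sorted(matrix_ids ^ meta_ids)
        raise ValueError(f"sample-id mismatch between matrix and metadata: {missing}")

    # align matrix columns to the metadata file order, never the reverse
    values = values[list(meta["sample_id"])]

    n0 = values.shape[0]
    values = values.dropna(axis=0, how="any")
    dropped = n0 - values.shape[0]
    if dropped:
        logger.info("dropped %d feature(s) with missing values", dropped)

    if log_transform:
        if (values.to_numpy() <= 0).any():
            raise ValueError("non-positive intensity under log_transform")
        values = np.log(values)

    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError("non-finite intensity values after filtering")

    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            group=str(row.group),
            genotype=str(row.genotype),
            treatment=str(row.treatment),
            replicate=int(row.replicate),
        )
        for row in meta.itertuples()
    ]
    return IntensityMatrix(values, samples)


def write_intensity_table(
    data: IntensityMatrix, matrix_path: str | Path, meta_path: str | Path
) -> None:
    """Write the matrix (TSV/CSV by extension) and metadata CSV."""
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    out = data.values.copy()
    out.index.name = "feature_id"
    # %.17g guarantees bit-exact float round-trips through text
    out.to_csv(matrix_path, sep=_sep_for(matrix_path), float_format="%.17g")
    data.meta_frame().to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# Comparison construction
# ---------------------------------------------------------------------------

def build_comparisons(samples: Sequence[SampleMeta]) -> list[Comparison]:
    """Build the pairwise contrasts implied by the sample metadata.

    For a 2x2 genotype x treatment factorial this yields four comparisons,
    two per axis: within each treatment level the two genotypes are compared
    (axis ``genotype``), and within each genotype the two treatments are
    compared (axis ``treatment``).  The first-listed group (y = 1) is the
    first-observed level in the metadata.  For plain two-group metadata a
    single comparison is returned.
    """
    samples = list(samples)

    def _levels(vals: Sequence[str]) -> list[str]:
        seen: list[str] = []
        for v in vals:
            if v not in seen:
                seen.append(v)
        return seen

    groups = _levels([s.group for s in samples])
    genotypes = _levels([s.genotype for s in samples])
    treatments = _levels([s.treatment for s in samples])

    if len(genotypes) == 2 and len(treatments) == 2 and len(groups) > 2:
        by_cell: dict[tuple[str, str], str] = {}
        for s in samples:
            by_cell[(s.genotype, s.treatment)] = s.group
        for g in genotypes:
            for t in treatments:
                if (g, t) not in by_cell:
                    raise ValueError(f"missing factorial cell: genotype={g}, treatment={t}")
        out = []
        for t in treatments:
            a, b = by_cell[(genotypes[0], t)], by_cell[(genotypes[1], t)]
            out.append(Comparison(f"{a}_vs_{b}", a, b, axis="genotype"))
        for g in genotypes:
            a, b = by_cell[(g, treatments[0])], by_cell[(g, treatments[1])]
            out.append(Comparison(f"{a}_vs_{b}", a, b, axis="treatment"))
        return out

    if len(groups) == 2:
        return [Comparison(f"{groups[0]}_vs_{groups[1]}", groups[0], groups[1])]

    raise ValueError(
        f"cannot derive comparisons from {len(groups)} groups "
        f"({len(genotypes)} genotypes x {len(treatments)} treatments)"
    )
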