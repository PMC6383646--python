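"""Domain types and CSV input/output for aggregate and individual-participant data.

The observed data of a superordinate-category meta-analysis are, per sample
``s``: a sample size ``N_s``, a diagnosed count ``n_{s,d}`` for every disorder
``d`` the sample measured (missing otherwise), optionally a count of
participants with at least one measured disorder ("any" count), and optionally
an individual-participant block of binary diagnoses ``y_{s,d,i}``.  Samples
drawn from the same parent study share a cluster label so that downstream
models can treat them as reporting a single set of study-level prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DisorderPanel",
    "AggregateSample",
    "IPDBlock",
    "MetaDataset",
    "load_dataset",
    "write_dataset",
    "measured_disorders",
]


@dataclass(frozen=True)
class DisorderPanel:
    """Ordered panel of the D disorders defining the superordinate category."""

    names: tuple[str, ...]

    def __init__(self, names: Sequence[str]):
        object.__setattr__(self, "names", tuple(str(n) for n in names))
        if len(set(self.names)) != len(self.names):
            raise ValueError("disorder labels must be unique")
        if len(self.names) < 1:
            raise ValueError("panel must contain at least one disorder")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def require_multivariate(self) -> None:
        """Raise for D = 1: a single disorder degenerates to a univariate model."""
        if len(self) < 2:
            raise ValueError(
                "multivariate operations require a panel of at least two disorders"
            )


@dataclass
class AggregateSample:
    """One sample's aggregate counts; ``None`` marks an unmeasured disorder."""

    sample_id: str
    cluster_id: str
    N: int
    counts: tuple[Optional[int], ...]
    any_count: Optional[int] = None
    ipd_available: bool = False

    def __post_init__(self) -> None:
        self.counts = tuple(None if c is None else int(c) for c in self.counts)
        if self.N < 0:
            raise ValueError(f"{self.sample_id}: negative sample size")
        for c in self.counts:
            if c is not None and not (0 <= c <= self.N):
                raise ValueError(
                    f"{self.sample_id}: disorder count {c} outside [0, N={self.N}]"
                )
        if self.n_measured < 1:
            raise ValueError(f"{self.sample_id}: no disorder measured")
        if self.any_count is not None:
            observed = [c for c in self.counts if c is not None]
            if not (0 <= self.any_count <= self.N):
                raise ValueError(f"{self.sample_id}: any_count outside [0, N]")
            if observed and self.any_count < max(observed):
                raise ValueError(
                    f"{self.sample_id}: any_count {self.any_count} below the "
                    f"largest per-disorder count {max(observed)}"
                )

    @property
    def n_measured(self) -> int:
        return sum(c is not None for c in self.counts)

    @property
    def measured_mask(self) -> np.ndarray:
        return np.array([c is not None for c in self.counts], dtype=bool)


def measured_disorders(sample: AggregateSample) -> int:
    """Number of disorders with an observed count in ``sample``."""
    return sample.n_measured


@dataclass
class IPDBlock:
    """Participant-level binary diagnoses for one sample.

    ``diagnoses`` is a participants x D float array; entries are 0.0, 1.0 or
    NaN, and missingness is column-wise (a disorder is measured for everyone
    in the sample or for no one).
    """

    sample_id: str
    diagnoses: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.diagnoses, dtype=float)
        if y.ndim != 2:
            raise ValueError(f"{self.sample_id}: diagnoses must be 2-D")
        finite = y[np.isfinite(y)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError(f"{self.sample_id}: IPD entries must be 0, 1 or missing")
        col_missing = np.isnan(y).sum(axis=0)
        partial = (col_missing > 0) & (col_missing < y.shape[0])
        if partial.any():
            raise ValueError(
                f"{self.sample_id}: missingness must be column-wise "
                f"(columns {np.where(partial)[0].tolist()} are partially observed)"
            )
        if not np.isfinite(y).any(axis=0).any():
            raise ValueError(f"{self.sample_id}: IPD block measures no disorder")
        self.diagnoses = y

    @property
    def measured_mask(self) -> np.ndarray:
        return np.isfinite(self.diagnoses).all(axis=0)

    def column_sums(self) -> np.ndarray:
        """Per-disorder diagnosed counts (NaN for unmeasured columns)."""
        out = np.full(self.diagnoses.shape[1], np.nan)
        m = self.measured_mask
        out[m] = self.diagnoses[:, m].sum(axis=0)
        return out


@dataclass
class MetaDataset:
    """A validated meta-analytic dataset: panel, aggregate samples, optional IPD."""

    panel: DisorderPanel
    samples: list[AggregateSample]
    ipd: list[IPDBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        D = len(self.panel)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in aggregate data")
        for s in self.samples:
            if len(s.counts) != D:
                raise ValueError(f"{s.sample_id}: expected {D} disorder columns")
        by_id = {s.sample_id: s for s in self.samples}
        seen = set()
        for block in self.ipd:
            if block.sample_id not in by_id:
                raise ValueError(f"IPD block {block.sample_id} has no aggregate sample")
            if block.sample_id in seen:
                raise ValueError(f"duplicate IPD block {block.sample_id}")
            seen.add(block.sample_id)
            s = by_id[block.sample_id]
            if block.diagnoses.shape != (s.N, D):
                raise ValueError(
                    f"{block.sample_id}: IPD shape {block.diagnoses.shape} does not "
                    f"match (N={s.N}, D={D})"
                )
            sums = block.column_sums()
            for d in range(D):
                agg, ipd_sum = s.counts[d], sums[d]
                if agg is not None and np.isfinite(ipd_sum) and agg != int(ipd_sum):
                    raise ValueError(
                        f"{block.sample_id}: aggregate count {agg} for "
                        f"'{self.panel.names[d]}' differs from IPD column sum "
                        f"{int(ipd_sum)}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def cluster_ids(self) -> list[str]:
        """Distinct cluster labels in order of first appearance."""
        out: list[str] = []
        for s in self.samples:
            if s.cluster_id not in out:
                out.append(s.cluster_id)
        return out

    def ipd_for(self, sample_id: str) -> Optional[IPDBlock]:
        for block in self.ipd:
            if block.sample_id == sample_id:
                return block
        return None

    def subset(self, keep: Sequence[str]) -> "MetaDataset":
        keep_set = set(keep)
        samples = [s for s in self.samples if s.sample_id in keep_set]
        ipd = [b for b in self.ipd if b.sample_id in keep_set]
        return MetaDataset(self.panel, samples, ipd)

    def to_frame(self) -> pd.DataFrame:
        """Aggregate data as a DataFrame in the canonical CSV column order."""
        rows = []
        for s in self.samples:
            row: dict = {
                "sample_id": s.sample_id,
                "cluster_id": s.cluster_id,
                "N": s.N,
                "any_count": s.any_count,
            }
            for d, name in enumerate(self.panel.names):
                row[name] = s.counts[d]
            rows.append(row)
        return pd.DataFrame(rows)


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    f = float(value)
    if f != int(f):
        raise ValueError(f"count {value!r} is not an integer")
    return int(f)


def load_dataset(
    aggregate_path: str | Path,
    ipd_path: Optional[str | Path] = None,
    panel: Optional[DisorderPanel] = None,
) -> MetaDataset:
    """Read a dataset from the aggregate CSV (and optional long-form IPD CSV).

    The aggregate schema is ``sample_id, cluster_id, N, any_count,
    <disorder_1> ... <disorder_D>`` with empty cells for unmeasured disorders;
    the IPD schema is ``sample_id, participant_id, <disorder_1> ...
    <disorder_D>`` with 0/1/empty cells.  If ``panel`` is omitted it is taken
    from the aggregate header.
    """
    agg = pd.read_csv(aggregate_path, dtype={"sample_id": str, "cluster_id": str})
    fixed = ["sample_id", "cluster_id", "N", "any_count"]
    missing_cols = [c for c in fixed if c not in agg.columns]
    if missing_cols:
        raise ValueError(f"aggregate CSV lacks required columns {missing_cols}")
    disorder_cols = [c for c in agg.columns if c not in fixed]
    if panel is None:
        panel = DisorderPanel(disorder_cols)
    else:
        if list(panel.names) != disorder_cols:
            raise ValueError(
                f"aggregate CSV disorder columns {disorder_cols} do not match "
                f"panel {list(panel.names)}"
            )
    samples = []
    for _, row in agg.iterrows():
        samples.append(
            AggregateSample(
                sample_id=str(row["sample_id"]),
                cluster_id=str(row["cluster_id"]),
                N=int(row["N"]),
                counts=tuple(_opt_int(row[c]) for c in panel.names),
                any_count=_opt_int(row["any_count"]),
            )
        )

    blocks: list[IPDBlock] = []
    if ipd_path is not None:
        ipd = pd.read_csv(ipd_path, dtype={"sample_id": str})
        for sid, grp in ipd.groupby("sample_id", sort=False):
            grp = grp.sort_values("participant_id")
            y = grp[list(panel.names)].to_numpy(dtype=float)
            blocks.append(IPDBlock(sample_id=str(sid), diagnoses=y))
        for s in samples:
            if any(b.sample_id == s.sample_id for b in blocks):
                s.ipd_available = True
    return MetaDataset(panel, samples, blocks)


def write_dataset(
    data: MetaDataset,
    aggregate_path: str | Path,
    ipd_path: Optional[str | Path] = None,
) -> None:
    """Write the dataset back in the same CSV dialects ``load_dataset`` reads."""
    df = data.to_frame()
    int_cols = ["any_count", *data.panel.names]
    df[int_cols] = df[int_cols].astype("Int64")  # keeps empty cells empty
    df.to_csv(aggregate_path, index=False)
    if ipd_path is not None:
        rows = []
        for block in data.ipd:
            for i, row in enumerate(block.diagnoses):
                rec = {"sample_id": block.sample_id, "participant_id": i}
                for d, name in enumerate(data.panel.names):
                    rec[name] = None if np.isnan(row[d]) else int(row[d])
                rows.append(rec)
        ipd_df = pd.DataFrame(rows)
        if len(ipd_df):
            ipd_df[list(data.panel.names)] = ipd_df[list(data.panel.names)].astype(
                "Int64"
            )
        ipd_df.to_csv(ipd_path, index=False)
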