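"""Gene x sample expression container for stress time-course experiments.

The canonical layout is one row per gene and one column per
(time point, replicate) sample.  Values are log2-scale expression by
default; every correlation and differential-expression computation in
this package operates on this container.

Sample identifiers follow the dialect ``t<hours>h_r<replicate>``,
e.g. ``t0h_r1`` for the first replicate of the 0 h control.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_SAMPLE_RE = re.compile(r"^t(?P<time>\d+(?:\.\d+)?)h_r(?P<rep>\d+)$")


def format_sample_id(time_point: float, replicate: int) -> str:
    """Render a (time point in hours, replicate) pair as a sample ID."""
    t = float(time_point)
    t_str = str(int(t)) if t == int(t) else repr(t)
    return f"t{t_str}h_r{int(replicate)}"


def parse_sample_id(sample_id: str) -> tuple[float, int]:
    """Parse ``t<hours>h_r<rep>`` into (hours, replicate)."""
    m = _SAMPLE_RE.match(sample_id)
    if m is None:
        raise ValueError(
            f"unparseable sample ID {sample_id!r}; expected 't<hours>h_r<rep>'"
        )
    return float(m.group("time")), int(m.group("rep"))


class ExpressionMatrix:
    """Genes x samples expression values with per-sample time/replicate metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per sample ID
        (``t<hours>h_r<rep>`` dialect).
    """

    def __init__(self, values: pd.DataFrame):
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise ValueError("expression matrix must have at least one gene and one sample")
        dup_genes = values.index[values.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene IDs: {dup_genes}")
        meta = [parse_sample_id(str(c)) for c in values.columns]
        if len(set(meta)) != len(meta):
            dups = [m for m, c in Counter(meta).items() if c > 1]
            raise ValueError(f"duplicate (time_point, replicate) pairs: {dups}")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = values.index[~np.isfinite(arr).all(axis=1)].tolist()
            raise ValueError(f"non-finite expression values for genes: {bad}")
        reps_per_time = Counter(t for t, _ in meta)
        if len(set(reps_per_time.values())) != 1:
            raise ValueError(
                f"unequal replicate counts across time points: {dict(reps_per_time)}"
            )
        self.values = values.astype(float)
        self._meta = meta

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        gene_ids: Sequence[str],
        values: np.ndarray,
        time_points: Sequence[float],
        replicates: Sequence[int],
    ) -> "ExpressionMatrix":
        """Build from a raw array plus per-column time/replicate labels."""
        cols = [format_sample_id(t, r) for t, r in zip(time_points, replicates)]
        df = pd.DataFrame(np.asarray(values, dtype=float), index=list(gene_ids), columns=cols)
        df.index.name = "gene_id"
        return cls(df)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Read the TSV dialect (first column gene ID, sample-ID header)."""
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                             float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: empty expression file") from None
        if df.shape[1] == 0:
            raise ValueError(f"{path}: no sample columns found")
        arr = df.to_numpy()
        # pandas fills ragged rows with NaN; report the first offending line
        try:
            bad = np.flatnonzero(~np.isfinite(arr.astype(float)).all(axis=1))
        except (TypeError, ValueError):
            raise ValueError(f"{path}: non-numeric expression values") from None
        if bad.size:
            raise ValueError(
                f"{path}: line {bad[0] + 2}: ragged or non-numeric row "
                f"for gene {df.index[bad[0]]!r}"
            )
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"{path}: duplicate gene IDs: {dup}")
        df.index.name = "gene_id"
        return cls(df)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        # %.17g guarantees an exact value round trip through text
        out.to_csv(path, sep="\t", float_format="%.17g")

    # ------------------------------------------------------------------
    # metadata accessors
    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def sample_times(self) -> list[float]:
        return [t for t, _ in self._meta]

    @property
    def sample_replicates(self) -> list[int]:
        return [r for _, r in self._meta]

    @property
    def time_points(self) -> list[float]:
        return sorted({t for t, _ in self._meta})

    @property
    def n_replicates(self) -> int:
        return Counter(t for t, _ in self._meta).most_common(1)[0][1]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index

    # ------------------------------------------------------------------
    # views
    # ------------------------------------------------------------------
    def gene_values(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not in expression matrix")
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def submatrix(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Values for the given genes as an array in the given order."""
        ids = list(gene_ids)
        missing = [g for g in ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        return self.values.loc[ids].to_numpy(dtype=float)

    def columns_at_time(self, time_point: float) -> list[str]:
        return [c for c, (t, _) in zip(self.sample_ids, self._meta) if t == time_point]

    def collapse_replicates(self) -> "ExpressionMatrix":
        """Average replicates, producing one column per time point."""
        parts = {}
        for t in self.time_points:
            cols = self.columns_at_time(t)
            parts[format_sample_id(t, 1)] = self.values[cols].mean(axis=1)
        df = pd.DataFrame(parts, index=self.values.index)
        df.index.name = "gene_id"
        return ExpressionMatrix(df)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ExpressionMatrix {self.n_genes} genes x {self.n_samples} samples "
            f"({len(self.time_points)} time points x {self.n_replicates} replicates)>"
        )
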