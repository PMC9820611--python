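"""Classification and bookkeeping of experimentally tested TF->target interactions.

An interaction is *direct* when ChIP-PCR shows the TF binding any of the
four 500 bp quarters of the target's 2000 bp promoter; *indirect* when no
fragment binds but overexpressing the TF changes the target's expression
by qRT-PCR (fold change > 2, p < 0.05, both strict); *none* when neither
holds; *untested* when no binding was seen and no qRT data exist.
Summaries report counts and one-decimal percentages, including the
"true" rate (direct + indirect).

Also provides the comparative-CT (2^-ddCt) relative-expression
arithmetic used for the qRT-PCR readout, with the reference-gene ΔCt
normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .util import round_half_up

__all__ = [
    "ValidationRecord",
    "ValidationSummary",
    "classify_interaction",
    "summarize_validation",
    "ddct_fold_change",
    "delta_ct_test",
]

LABELS = ("direct", "indirect", "none", "untested")


def classify_interaction(
    chip_fragments: Sequence[bool],
    qrt_fold_change: float | None = None,
    qrt_p: float | None = None,
) -> str:
    """Label one tested interaction from its assay outcomes.

    Any bound promoter fragment makes the interaction direct regardless
    of expression data; fragment order is immaterial.  fold change = 2
    exactly is not indirect (strict >).
    """
    frags = [bool(f) for f in chip_fragments]
    if not frags:
        raise ValueError("chip_fragments must contain at least one fragment outcome")
    if qrt_fold_change is not None:
        if not math.isfinite(qrt_fold_change) or qrt_fold_change <= 0:
            raise ValueError(f"fold change must be a positive real, got {qrt_fold_change}")
    if qrt_p is not None:
        if not math.isfinite(qrt_p) or not (0 <= qrt_p <= 1):
            raise ValueError(f"p-value must be in [0, 1], got {qrt_p}")
    if any(frags):
        return "direct"
    if qrt_fold_change is None or qrt_p is None:
        return "untested"
    if qrt_fold_change > 2 and qrt_p < 0.05:
        return "indirect"
    return "none"


@dataclass(frozen=True)
class ValidationRecord:
    """One tested TF->target interaction and its assay outcomes."""

    tf_id: str
    target_id: str
    layer_pair: str  # "1->2" or "2->3"
    chip_fragments: tuple[bool, bool, bool, bool]
    qrt_fold_change: float | None = None
    qrt_p: float | None = None

    def __post_init__(self):
        if self.layer_pair not in ("1->2", "2->3"):
            raise ValueError(f"layer_pair must be '1->2' or '2->3', got {self.layer_pair!r}")
        if len(self.chip_fragments) != 4:
            raise ValueError("expected 4 promoter-quarter fragment outcomes")

    @property
    def label(self) -> str:
        return classify_interaction(self.chip_fragments, self.qrt_fold_change, self.qrt_p)


@dataclass(frozen=True)
class ValidationSummary:
    """Counts and one-decimal percentages over labeled records."""

    n_tested: int
    n_direct: int
    n_indirect: int
    n_none: int
    pct_direct: float
    pct_indirect: float
    pct_none: float
    pct_true: float

    def to_dict(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_direct": self.n_direct,
            "n_indirect": self.n_indirect,
            "n_none": self.n_none,
            "pct_direct": self.pct_direct,
            "pct_indirect": self.pct_indirect,
            "pct_none": self.pct_none,
            "pct_true": self.pct_true,
        }

    def to_text(self) -> str:
        return "\n".join([
            "Interaction validation summary",
            "------------------------------",
            f"tested:    {self.n_tested}",
            f"direct:    {self.n_direct} ({self.pct_direct}%)",
            f"indirect:  {self.n_indirect} ({self.pct_indirect}%)",
            f"none:      {self.n_none} ({self.pct_none}%)",
            f"true (direct + indirect): {self.pct_true}%",
        ])


def summarize_validation(records: Iterable[ValidationRecord]) -> ValidationSummary:
    """Counts and percentages (half-up, one decimal) over fully tested records."""
    recs = list(records)
    if not recs:
        raise ValueError("no validation records to summarize")
    counts = {"direct": 0, "indirect": 0, "none": 0}
    for r in recs:
        label = r.label
        if label == "untested":
            raise ValueError(f"record {r.tf_id}->{r.target_id} is untested")
        counts[label] += 1
    n = len(recs)
    pct = lambda c: round_half_up(100.0 * c / n, 1)  # noqa: E731
    return ValidationSummary(
        n_tested=n,
        n_direct=counts["direct"],
        n_indirect=counts["indirect"],
        n_none=counts["none"],
        pct_direct=pct(counts["direct"]),
        pct_indirect=pct(counts["indirect"]),
        pct_none=pct(counts["none"]),
        pct_true=pct(counts["direct"] + counts["indirect"]),
    )


def ddct_fold_change(
    ct_target_treated,
    ct_reference_treated,
    ct_target_control,
    ct_reference_control,
) -> float:
    """Relative expression by the comparative-CT method, 2^-ddCt.

    Arguments may be scalars or per-replicate vectors (averaged first).
    dCt = Ct(target) - Ct(reference) within each condition;
    ddCt = dCt(treated) - dCt(control).
    """
    def mean_ct(v, name):
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if arr.size == 0 or not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name}: Ct values must be positive finite reals")
        return float(arr.mean())

    dct_treated = mean_ct(ct_target_treated, "ct_target_treated") - mean_ct(
        ct_reference_treated, "ct_reference_treated")
    dct_control = mean_ct(ct_target_control, "ct_target_control") - mean_ct(
        ct_reference_control, "ct_reference_control")
    return float(2.0 ** (-(dct_treated - dct_control)))


def delta_ct_test(delta_ct_treated, delta_ct_control) -> float:
    """Convenience Welch t-test p-value on replicate ΔCt values."""
    t = np.asarray(delta_ct_treated, dtype=float)
    c = np.asarray(delta_ct_control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("need >= 2 replicate ΔCt values per condition")
    if t.var(ddof=1) == 0 and c.var(ddof=1) == 0:
        return 1.0 if t.mean() == c.mean() else 0.0
    return float(stats.ttest_ind(t, c, equal_var=False).pvalue)
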