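"""Planted three-layer regulator hierarchies and simulated stress time courses.

The generator produces a ground-truth network whose topology mirrors the
hierarchies this package infers: a small set of top-layer transcription
factors (TFs) driving a middle layer of TFs, which in turn drive a large
bottom layer of structural genes.  The simulator then propagates smooth
random temporal driver profiles down the hierarchy by signed linear
mixing and adds Gaussian noise on the log-expression scale, so that
co-regulated genes share a common driver — the statistical structure the
partial-correlation attribution assumes.

Noise is propagated through the *observed* parent expression: a target is
a standardized mixture of its parents' noisy, replicate-matched values
plus its own intrinsic noise.  Under this model the partial correlation
of two co-regulated siblings given their true regulator is ~0, so the
triple-gene test is consistent; mixing noise-free parent profiles instead
would leave a residual shared signal and pin that partial correlation
near 0.5 no matter how small the noise (see docs/methods.md).  At
``noise_sd = 0`` the two formulations coincide exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .expression import ExpressionMatrix

__all__ = [
    "PlantedGRN",
    "SimulationConfig",
    "RecoveryReport",
    "generate_planted_grn",
    "simulate_time_course",
    "score_recovery",
]


# ----------------------------------------------------------------------
# planted ground truth
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PlantedGRN:
    """Ground-truth three-layer hierarchy with signed regulator->target weights."""

    layer1_ids: tuple[str, ...]
    layer2_ids: tuple[str, ...]
    layer3_ids: tuple[str, ...]
    edges: Mapping[tuple[str, str], float]  # (regulator, target) -> signed weight
    seed: int

    def __post_init__(self):
        l1, l2, l3 = set(self.layer1_ids), set(self.layer2_ids), set(self.layer3_ids)
        if not (l1 and l2 and l3):
            raise ValueError("all three layers must be non-empty")
        if l1 & l2 or l1 & l3 or l2 & l3:
            raise ValueError("layers must be pairwise disjoint")
        out_deg: dict[str, int] = {g: 0 for g in l1 | l2}
        in_deg: dict[str, int] = {g: 0 for g in l2 | l3}
        for (reg, tgt), w in self.edges.items():
            if w == 0:
                raise ValueError(f"zero weight on edge {reg}->{tgt}")
            if reg in l1 and tgt in l2:
                pass
            elif reg in l2 and tgt in l3:
                pass
            else:
                raise ValueError(f"edge {reg}->{tgt} is not layer1->2 or layer2->3")
            out_deg[reg] += 1
            in_deg[tgt] += 1
        lonely_out = sorted(g for g, d in out_deg.items() if d == 0)
        if lonely_out:
            raise ValueError(f"regulators without outgoing edges: {lonely_out}")
        lonely_in = sorted(g for g, d in in_deg.items() if d == 0)
        if lonely_in:
            raise ValueError(f"targets without incoming edges: {lonely_in}")

    @property
    def edges_12(self) -> set[tuple[str, str]]:
        l1 = set(self.layer1_ids)
        return {(r, t) for (r, t) in self.edges if r in l1}

    @property
    def edges_23(self) -> set[tuple[str, str]]:
        l2 = set(self.layer2_ids)
        return {(r, t) for (r, t) in self.edges if r in l2}

    def parents_of(self, gene_id: str) -> list[tuple[str, float]]:
        return sorted(
            ((r, w) for (r, t), w in self.edges.items() if t == gene_id)
        )

    @property
    def all_gene_ids(self) -> list[str]:
        return list(self.layer1_ids) + list(self.layer2_ids) + list(self.layer3_ids)

    def to_edge_tsv(self, path) -> None:
        """Write the edge list: regulator, target, weight, layer_pair."""
        l1 = set(self.layer1_ids)
        with open(path, "w") as fh:
            fh.write("regulator\ttarget\tweight\tlayer_pair\n")
            for (r, t) in sorted(self.edges):
                pair = "1->2" if r in l1 else "2->3"
                fh.write(f"{r}\t{t}\t{self.edges[(r, t)]!r}\t{pair}\n")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of the simulated stress time course.

    Defaults mirror a 7-point PEG-stress experiment (0/1/3/5/9/12/24 h,
    0 h control) with three biological replicates and small intrinsic
    noise on the log2 scale.
    """

    time_points: tuple[float, ...] = (0.0, 1.0, 3.0, 5.0, 9.0, 12.0, 24.0)
    n_replicates: int = 3
    noise_sd: float = 0.05
    driver_smoothness: int = 3
    seed: int = 0
    intrinsic_sd: float = 1.0  # gene-intrinsic smooth variation of middle-layer TFs
    lag: int = 0  # per-edge propagation delay in time-point units
    profile_mode: str = "smooth"  # "smooth" or "patterns"

    def __post_init__(self):
        tp = tuple(float(t) for t in self.time_points)
        if any(t < 0 for t in tp):
            raise ValueError("time points must be non-negative hours")
        if list(tp) != sorted(set(tp)):
            raise ValueError("time points must be strictly increasing")
        if tp and tp[0] != 0.0:
            raise ValueError("first time point must be the 0 h control")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.intrinsic_sd < 0:
            raise ValueError("intrinsic_sd must be non-negative")
        if self.driver_smoothness < 1:
            raise ValueError("driver_smoothness must be a positive integer")
        if self.profile_mode not in ("smooth", "patterns"):
            raise ValueError("profile_mode must be 'smooth' or 'patterns'")
        object.__setattr__(self, "time_points", tp)


# ----------------------------------------------------------------------
# topology generation
# ----------------------------------------------------------------------
def _draw_weight(rng: np.random.Generator, positive_prob: float,
                 magnitude: tuple[float, float]) -> float:
    w = rng.uniform(*magnitude)
    return w if rng.random() < positive_prob else -w


def generate_planted_grn(
    n1: int,
    n2: int,
    n3: int,
    mean_out_degree: float,
    seed: int,
    positive_weight_prob: float = 0.8,
    weight_magnitude: tuple[float, float] = (0.5, 1.5),
) -> PlantedGRN:
    """Sample a random three-layer hierarchy.

    Every layer-2/3 gene receives one uniformly chosen parent, regulators
    left childless are given one, then extra edges are added
    regulator-centrically (a uniformly chosen regulator with spare
    capacity gains one unused downstream target) until the mean
    out-degree over all n1+n2 regulators is met.  Weight magnitudes are
    uniform on [0.5, 1.5]; signs are positive with probability 0.8
    (stress regulons are predominantly coherently activated).
    """
    if n1 < 1 or n2 < 1 or n3 < 2:
        raise ValueError("require n1 >= 1, n2 >= 1, n3 >= 2")
    if mean_out_degree < 1:
        raise ValueError("mean_out_degree must be >= 1")
    capacity = n1 * n2 + n2 * n3
    target_total = int(round(mean_out_degree * (n1 + n2)))
    if target_total > capacity:
        raise ValueError(
            f"mean_out_degree {mean_out_degree} needs {target_total} edges; "
            f"maximum possible is {capacity}"
        )

    rng = np.random.default_rng(seed)
    layer1 = tuple(f"TF1_{i + 1:02d}" for i in range(n1))
    layer2 = tuple(f"TF2_{i + 1:02d}" for i in range(n2))
    layer3 = tuple(f"SG_{i + 1:03d}" for i in range(n3))

    edges: dict[tuple[str, str], float] = {}

    def add_edge(reg: str, tgt: str) -> None:
        edges[(reg, tgt)] = _draw_weight(rng, positive_weight_prob, weight_magnitude)

    # middle-layer TFs integrate >= 2 upstream inputs when available, with
    # distinct parent pairs where possible, so no two regulator profiles
    # are near-copies of each other; bottom-layer genes get one parent each
    if n1 >= 2:
        from itertools import combinations

        all_pairs = list(combinations(range(n1), 2))
        if len(all_pairs) >= n2:
            chosen = rng.choice(len(all_pairs), size=n2, replace=False)
            parent_sets = [all_pairs[c] for c in chosen]
        else:
            parent_sets = [tuple(rng.choice(n1, size=2, replace=False))
                           for _ in range(n2)]
    else:
        parent_sets = [(0,) for _ in range(n2)]
    for tgt, pset in zip(layer2, parent_sets):
        for reg_i in pset:
            add_edge(layer1[reg_i], tgt)
    for tgt in layer3:
        add_edge(layer2[rng.integers(n2)], tgt)

    # guarantee every regulator one child
    for reg_pool, tgt_pool in ((layer1, layer2), (layer2, layer3)):
        childless = [r for r in reg_pool if not any((r, t) in edges for t in tgt_pool)]
        for reg in childless:
            free = [t for t in tgt_pool if (reg, t) not in edges]
            add_edge(reg, free[rng.integers(len(free))])

    # top up to the requested mean out-degree
    downstream = {**{r: layer2 for r in layer1}, **{r: layer3 for r in layer2}}
    regs = list(layer1) + list(layer2)
    while len(edges) < target_total:
        open_regs = [
            r for r in regs
            if sum((r, t) in edges for t in downstream[r]) < len(downstream[r])
        ]
        reg = open_regs[rng.integers(len(open_regs))]
        free = [t for t in downstream[reg] if (reg, t) not in edges]
        add_edge(reg, free[rng.integers(len(free))])

    return PlantedGRN(layer1, layer2, layer3, edges, seed)


# ----------------------------------------------------------------------
# expression simulation
# ----------------------------------------------------------------------
_PATTERNS = {
    # archetype driver shapes on normalized time u in [0, 1]:
    # up-early / down-late, down-early / up-late, oscillating
    0: lambda u: np.sin(np.pi * u) - 1.2 * u,
    1: lambda u: -np.sin(np.pi * u) + 1.2 * u,
    2: lambda u: np.sin(3 * np.pi * u),
}


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate (zero-variance) profile")
    return (v - v.mean()) / sd


_DRIVER_COHERENCE = 0.45  # max |corr| tolerated between two planted drivers


def _raw_profile(rng: np.random.Generator, n_times: int, k: int) -> np.ndarray:
    """Smooth random temporal profile: sum of random low-frequency cosine modes.

    Modes are discrete-cosine basis vectors on the sampling-order grid
    (exactly orthogonal over the time points, so random profiles are
    isotropic in their span rather than collapsing onto one dominant
    shape); ``k`` mode pairs give a 2k-dimensional profile family.
    """
    i = np.arange(n_times)
    n_modes = min(2 * k, n_times - 1)
    for _ in range(100):
        prof = np.zeros(n_times)
        for j in range(1, n_modes + 1):
            prof += rng.normal() * np.cos(np.pi * j * (i + 0.5) / n_times)
        if prof.std() > 1e-9:
            return _standardize(prof)
    raise RuntimeError("failed to draw a non-degenerate driver profile")


def _driver_profile(rng: np.random.Generator, u: np.ndarray, k: int,
                    mode: str, index: int,
                    accepted: list[np.ndarray]) -> np.ndarray:
    """Draw one driver profile, kept pairwise separated from earlier drivers.

    Two near-collinear drivers would plant a ground truth no
    correlation-based method could attribute, so candidates are
    rejection-sampled until their |corr| with every accepted driver stays
    under a coherence cap (relaxed gradually when the time grid is too
    short to fit more well-separated profiles).
    """
    if mode == "patterns":
        return _standardize(_PATTERNS[index % 3](u))
    cap = _DRIVER_COHERENCE
    n = len(u)
    others = np.vstack(accepted) if accepted else None
    best, best_coh = None, np.inf
    for attempt in range(1, 801):
        prof = _raw_profile(rng, n, k)
        # profiles are standardized, so correlation is a dot product
        coh = 0.0 if others is None else float(np.max(np.abs(others @ prof))) / n
        if coh < best_coh:
            best, best_coh = prof, coh
        if coh <= cap:
            return prof
        if attempt % 100 == 0:
            cap = min(1.0, cap * 1.15)
    return best


def simulate_time_course(grn: PlantedGRN, config: SimulationConfig) -> ExpressionMatrix:
    """Simulate log2 expression for every gene in the planted network.

    Layer-1 drivers get smooth random temporal profiles; each downstream
    gene is the weighted sum of its parents' observed expression,
    rescaled to unit variance, plus i.i.d. Gaussian noise per sample.
    Deterministic given ``config.seed``.
    """
    times = config.time_points
    if len(times) < 3:
        raise ValueError("need at least 3 time points for defined correlation p-values")
    reps = config.n_replicates
    n_samples = len(times) * reps
    rng = np.random.default_rng(config.seed)
    u = np.asarray(times) / max(times)

    sample_times = [t for t in times for _ in range(reps)]
    sample_reps = [r + 1 for _ in times for r in range(reps)]

    def lagged(profile: np.ndarray) -> np.ndarray:
        if config.lag == 0:
            return profile
        # shift by whole time-point units, clamping at the series start
        idx = np.maximum(np.arange(len(times)) - config.lag, 0)
        return profile[idx]

    obs: dict[str, np.ndarray] = {}
    accepted: list[np.ndarray] = []
    for i, g in enumerate(grn.layer1_ids):
        prof = _driver_profile(rng, u, config.driver_smoothness,
                               config.profile_mode, i, accepted)
        accepted.append(prof)
        signal = np.repeat(prof, reps)
        obs[g] = signal + rng.normal(0.0, config.noise_sd, n_samples)

    # Middle-layer TFs carry gene-intrinsic smooth variation (inputs beyond
    # the modeled hierarchy) so that no two regulator profiles coincide —
    # the condition under which the planted attribution is identifiable.
    # Bottom-layer genes are faithful outputs of their regulators up to
    # replicate noise.
    for layer, intrinsic in ((grn.layer2_ids, config.intrinsic_sd),
                             (grn.layer3_ids, 0.0)):
        for g in layer:
            parents = grn.parents_of(g)
            mix = np.zeros(n_samples)
            for parent, w in parents:
                pv = obs[parent]
                if config.lag:
                    per_time = pv.reshape(len(times), reps)
                    pv = lagged(per_time).reshape(-1)
                mix += w * pv
            mix = _standardize(mix)
            if intrinsic > 0:
                # gene-intrinsic variation realized independently per
                # biological replicate (unmodeled inputs differ between
                # replicate plants); children inherit it through the
                # parent's observed expression, replicate-matched
                own = np.column_stack([
                    _raw_profile(rng, len(times), config.driver_smoothness)
                    for _ in range(reps)
                ]).reshape(-1)
                mix = mix + intrinsic * own
            obs[g] = mix + rng.normal(0.0, config.noise_sd, n_samples)

    genes = grn.all_gene_ids
    values = np.vstack([obs[g] for g in genes])
    return ExpressionMatrix.from_arrays(genes, values, sample_times, sample_reps)


def to_fpkm_like(matrix: ExpressionMatrix, base_log2: float = 6.0) -> ExpressionMatrix:
    """Exponentiate log2 values into FPKM-like positive expression."""
    import pandas as pd

    df = np.power(2.0, matrix.values + base_log2)
    df = pd.DataFrame(df, index=matrix.values.index, columns=matrix.values.columns)
    df.index.name = "gene_id"
    return ExpressionMatrix(df)


# ----------------------------------------------------------------------
# recovery scoring
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall/F1 of inferred edges against the planted truth, per layer pair."""

    precision_12: float
    recall_12: float
    f1_12: float
    precision_23: float
    recall_23: float
    f1_23: float
    n_inferred_12: int
    n_inferred_23: int
    n_planted_12: int
    n_planted_23: int


def _prf(inferred: set, planted: set) -> tuple[float, float, float]:
    tp = len(inferred & planted)
    precision = tp / len(inferred) if inferred else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    if math.isnan(precision) or math.isnan(recall):
        f1 = float("nan")
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def score_recovery(planted: PlantedGRN, inferred) -> RecoveryReport:
    """Score an inferred HierarchicalGRN (or plain edge sets) against the truth.

    ``inferred`` may be a :class:`hiergrn.grn.HierarchicalGRN` or any
    object with ``edges_12``/``edges_23`` sets of (source, target) pairs.
    Weights and signs are ignored; degenerate inputs yield NaN sentinels,
    never failures.
    """
    inf12 = set(inferred.edges_12)
    inf23 = set(inferred.edges_23)
    p12, r12, f12 = _prf(inf12, planted.edges_12)
    p23, r23, f23 = _prf(inf23, planted.edges_23)
    return RecoveryReport(
        precision_12=p12, recall_12=r12, f1_12=f12,
        precision_23=p23, recall_23=r23, f1_23=f23,
        n_inferred_12=len(inf12), n_inferred_23=len(inf23),
        n_planted_12=len(planted.edges_12), n_planted_23=len(planted.edges_23),
    )
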