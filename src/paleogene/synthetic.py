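"""Synthetic data with known ground truth for every pipeline stage.

Generates ultrametric trees (Yule topology rescaled to a chosen root age),
gene gain/loss histories propagated to leaf presence, alignment hit tables
whose identity/coverage straddle the 80/80 filter, and paleotemperature
curves — a cooling trend with injected warming excursions of known amplitude
and duration, sampled with the density increasing toward the present that
real compilations show.

Design notes:

* Each gene carries at most one gain (the dating rule outputs a single age
  per gene, so multiple independent gains would have no single truth).  With
  a positive gain rate the gain is placed uniformly over the tree's total
  branch length — the location of a single homogeneous Poisson event
  conditioned on one occurrence — so every gene is gained exactly once and
  branch choice is proportional to branch duration.
* ``ExcursionSpec.duration`` is the duration of the *rising limb*: the
  excursion climbs from age ``center + duration`` to its peak at ``center``
  and decays symmetrically afterwards.  The detector measures rises, so this
  is the quantity its duration threshold sees.
* All randomness flows through explicit integer seeds; no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .presence import AlignmentHit, ThresholdConfig
from .paleotemp import LwpConfig, TemperatureSeries, WarmingInterval
from .timetree import TimeTree, TreeNode

__all__ = [
    "GainLossEvent",
    "GeneHistoryTruth",
    "ExcursionSpec",
    "simulate_tree",
    "simulate_gene_histories",
    "simulate_hit_table",
    "simulate_temperature",
]

#: default synthetic scale, mirroring the study conditions: 32 primate
#: species, a 74-MYA root, 145 query genes, a 66-MY temperature span
DEFAULT_N_LEAVES = 32
DEFAULT_ROOT_AGE = 74.0
DEFAULT_N_GENES = 145
DEFAULT_OLDEST = 66.0


@dataclass(frozen=True)
class GainLossEvent:
    kind: str  # "gain" | "loss"
    node_id: int  # child node of the branch carrying the event
    age: float  # MYA, within (child age, parent age)


@dataclass
class GeneHistoryTruth:
    """Ground truth for one simulated gene."""

    gene: str
    events: list[GainLossEvent]
    #: leaf presence implied by the events
    presence: dict[str, bool]
    #: parent node of the branch carrying the gain (the true emergence node)
    true_node_id: int | None
    true_node_age: float | None
    true_gain_age: float | None


@dataclass(frozen=True)
class ExcursionSpec:
    """One injected warming excursion.

    The rising limb spans ages [center + duration, center]; the bump decays
    symmetrically over the same span toward the present, so the full support
    is [center - duration, center + duration].
    """

    center_age: float
    amplitude: float  # °C at the peak
    duration: float  # MY of the rising limb
    shape: str = "triangular"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.duration <= 0:
            raise ValueError("amplitude and duration must be > 0")
        if self.shape not in ("triangular", "gaussian"):
            raise ValueError(f"unknown excursion shape {self.shape!r}")

    @property
    def support(self) -> tuple[float, float]:
        return (self.center_age - self.duration, self.center_age + self.duration)

    def bump(self, age: np.ndarray) -> np.ndarray:
        """Temperature anomaly contributed at the given ages."""
        x = np.abs(np.asarray(age, dtype=float) - self.center_age)
        if self.shape == "triangular":
            ramp = 1.0 - x / self.duration
            # snap float dust at the limb endpoints to an exact zero so the
            # anomaly support is precisely [center - duration, center + duration]
            return self.amplitude * np.where(ramp > 1e-9, ramp, 0.0)
        sigma = self.duration / 2.0
        out = self.amplitude * np.exp(-0.5 * (x / sigma) ** 2)
        return np.where(x <= self.duration, out, 0.0)

    @property
    def net_rise_on_flat(self) -> float:
        """Net rise over the rising limb on a flat baseline."""
        if self.shape == "triangular":
            return self.amplitude
        return self.amplitude * (1.0 - math.exp(-2.0))


# ---------------------------------------------------------------------------
# trees


def simulate_tree(
    n_leaves: int = DEFAULT_N_LEAVES,
    root_age: float = DEFAULT_ROOT_AGE,
    seed: int = 0,
) -> TimeTree:
    """Yule (pure-birth) topology rescaled so the root sits at ``root_age``.

    Leaves are named ``sp01 .. spNN`` in tree order and sit at age 0;
    deterministic for a given seed.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    if root_age <= 0:
        raise ValueError("root_age must be > 0")
    rng = np.random.default_rng(seed)

    # forward simulation: split times of each lineage, birth rate 1
    # (absolute rate is irrelevant after rescaling)
    next_id = iter(range(10**9))
    root = TreeNode(id=next(next_id), name=None, age=0.0)
    active = [root]
    t = 0.0
    split_time: dict[int, float] = {}
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        split_time[node.id] = t
        kids = [
            TreeNode(id=next(next_id), name=None, age=0.0, parent=node)
            for _ in range(2)
        ]
        node.children = kids
        active.extend(kids)
    present = t + rng.exponential(1.0 / n_leaves)  # tips extend past last split

    scale = root_age / (present - split_time[root.id])
    counter = iter(range(1, n_leaves + 1))

    def finalize(node: TreeNode) -> None:
        if node.children:
            node.age = (present - split_time[node.id]) * scale
            for child in node.children:
                finalize(child)
        else:
            node.age = 0.0
            node.name = f"sp{next(counter):02d}"

    finalize(root)
    return TimeTree(root=root)


# ---------------------------------------------------------------------------
# gene histories


def _branches(tree: TimeTree) -> list[tuple[TreeNode, float]]:
    """(child node, branch length) for every non-root node, preorder."""
    return [
        (node, node.parent.age - node.age)
        for node in tree.nodes()
        if node.parent is not None
    ]


def _subtree_leaves(node: TreeNode) -> list[str]:
    return sorted(node.leaf_names())


def simulate_gene_histories(
    tree: TimeTree,
    n_genes: int = DEFAULT_N_GENES,
    gain_rate: float = 0.02,
    loss_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[GeneHistoryTruth]]:
    """Simulate reversible gain/loss histories and the implied presence matrix.

    Each gene receives exactly one gain (rate > 0) placed uniformly over the
    tree's total branch length (branch chosen proportionally to its
    duration, position uniform within the branch); losses then
    occur independently on branches below the gain with per-MY rate
    ``loss_rate`` (a lost lineage stays lost — re-gains are suppressed so the
    emergence node stays identifiable).  Returns the boolean gene × species
    matrix and per-gene ground truth.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    branches = _branches(tree)
    lengths = np.array([ln for _, ln in branches])
    total = float(lengths.sum())
    species = tree.leaf_names()
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]

    rows = []
    truths = []
    for gene in genes:
        events: list[GainLossEvent] = []
        present: dict[str, bool] = {sp: False for sp in species}
        true_node_id = true_node_age = true_gain_age = None

        if gain_rate > 0 and total > 0:
            # a homogeneous Poisson event conditioned on a single occurrence
            # is uniform over the tree's total branch length
            pos = rng.random() * total
            cum = np.cumsum(lengths)
            idx = int(np.searchsorted(cum, pos))
            gain_node, gain_len = branches[idx]
            offset = pos - (cum[idx] - gain_len)  # from the older (parent) end
            gain_age = gain_node.parent.age - offset
            events.append(GainLossEvent("gain", gain_node.id, gain_age))
            true_node_id = gain_node.parent.id
            true_node_age = gain_node.parent.age
            true_gain_age = gain_age

            # losses on branches strictly below the gained branch
            lost_subtrees: list[TreeNode] = []
            if loss_rate > 0:
                stack = list(gain_node.children)
                while stack:
                    node = stack.pop()
                    ln = node.parent.age - node.age
                    if rng.random() < 1.0 - math.exp(-loss_rate * ln):
                        loss_age = node.parent.age - rng.uniform(0.0, ln)
                        events.append(GainLossEvent("loss", node.id, loss_age))
                        lost_subtrees.append(node)  # stays lost below here
                    else:
                        stack.extend(node.children)

            for sp in _subtree_leaves(gain_node):
                present[sp] = True
            for node in lost_subtrees:
                for sp in _subtree_leaves(node):
                    present[sp] = False

        rows.append([present[sp] for sp in species])
        truths.append(
            GeneHistoryTruth(
                gene=gene,
                events=events,
                presence=dict(present),
                true_node_id=true_node_id,
                true_node_age=true_node_age,
                true_gain_age=true_gain_age,
            )
        )

    matrix = pd.DataFrame(rows, index=genes, columns=species, dtype=bool)
    return matrix, truths


# ---------------------------------------------------------------------------
# hit tables


def simulate_hit_table(
    presence: pd.DataFrame,
    id_mean: float = 95.0,
    id_sd: float = 3.0,
    cov_mean: float = 0.95,
    cov_sd: float = 0.04,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    decoy_rate: float = 0.1,
    seed: int = 0,
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> list[AlignmentHit]:
    """Emit TBLASTN-style hits whose filter outcome reproduces ``presence``.

    True-present cells yield a hit passing both thresholds with probability
    1 − ``fn_rate`` (otherwise a sub-threshold hit); true-absent cells yield a
    passing hit with probability ``fp_rate``, a sub-threshold decoy with
    probability ``decoy_rate``, else nothing.  With fp = fn = 0 the 80/80
    filter reconstructs the input matrix exactly.  Roughly half the hits are
    reported minus-strand (start > end).
    """
    rng = np.random.default_rng(seed)
    thr_id = thresholds.min_identity
    thr_cov = thresholds.min_subject_coverage / 100.0
    hits: list[AlignmentHit] = []

    def passing_values() -> tuple[float, float]:
        ident = float(np.clip(rng.normal(id_mean, id_sd), thr_id, 100.0))
        cov = float(np.clip(rng.normal(cov_mean, cov_sd), thr_cov, 1.0))
        return ident, cov

    def failing_values() -> tuple[float, float]:
        mode = rng.integers(3)  # fail identity, coverage, or both
        if mode == 0:
            return (
                float(rng.uniform(30.0, thr_id - 1.0)),
                float(rng.uniform(thr_cov, 1.0)),
            )
        if mode == 1:
            return (
                float(rng.uniform(thr_id, 100.0)),
                float(rng.uniform(0.2, thr_cov - 0.02)),
            )
        return (
            float(rng.uniform(30.0, thr_id - 1.0)),
            float(rng.uniform(0.2, thr_cov - 0.02)),
        )

    def emit(gene: str, sp: str, ident: float, cov: float, passing: bool) -> None:
        slen = int(rng.integers(300, 3000))
        span = math.ceil(cov * slen) if passing else max(1, math.floor(cov * slen))
        span = min(span, slen)
        start = int(rng.integers(1, slen - span + 2))
        end = start + span - 1
        if rng.random() < 0.5:
            start, end = end, start
        hits.append(
            AlignmentHit(
                query_gene=gene,
                subject_species=sp,
                subject_seq=f"{sp}|cds{rng.integers(1, 10**6)}",
                percent_identity=round(ident, 2),
                subject_start=start,
                subject_end=end,
                subject_length=slen,
            )
        )

    for gene in presence.index:
        for sp in presence.columns:
            if presence.loc[gene, sp]:
                if rng.random() < fn_rate:
                    emit(gene, sp, *failing_values(), passing=False)
                else:
                    emit(gene, sp, *passing_values(), passing=True)
            else:
                if rng.random() < fp_rate:
                    emit(gene, sp, *passing_values(), passing=True)
                elif rng.random() < decoy_rate:
                    emit(gene, sp, *failing_values(), passing=False)
    return hits


# ---------------------------------------------------------------------------
# temperature


def simulate_temperature(
    oldest: float = DEFAULT_OLDEST,
    trend_start: float = 26.0,
    trend_end: float = 14.0,
    excursions: Sequence[ExcursionSpec] = (),
    n_points: int = 400,
    density_power: float = 0.7,
    noise_sd: float = 0.0,
    seed: int = 0,
    lwp_cfg: LwpConfig = LwpConfig(),
) -> tuple[TemperatureSeries, list[WarmingInterval]]:
    """Cooling trend plus warming excursions, unevenly sampled.

    Sample ages are drawn with density ∝ (age + ε)^(−density_power), so
    spacing tightens toward the present as in real compilations; each
    excursion's limb endpoints and peak are always included so no excursion
    can fall between samples.  Returns the series and the truth: the
    excursion rising limbs that qualify under ``lwp_cfg`` (net rise computed
    on the trend-superimposed signal).
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    order = sorted(excursions, key=lambda e: -e.center_age)
    for a, b in zip(order, order[1:]):
        if a.support[0] < b.support[1]:
            raise ValueError(
                f"excursions at {a.center_age} and {b.center_age} MYA overlap"
            )
    for exc in order:
        lo, hi = exc.support
        if lo < 0 or hi > oldest:
            raise ValueError(
                f"excursion at {exc.center_age} MYA extends outside [0, {oldest}]"
            )

    rng = np.random.default_rng(seed)
    eps = 0.05
    p = density_power
    u = rng.random(n_points)
    if abs(p - 1.0) < 1e-12:
        ages = np.exp(
            np.log(eps) + u * (np.log(oldest + eps) - np.log(eps))
        ) - eps
    else:
        lo, hi = eps ** (1 - p), (oldest + eps) ** (1 - p)
        ages = (lo + u * (hi - lo)) ** (1.0 / (1 - p)) - eps
    ages = np.clip(ages, 0.0, oldest)

    anchor = [0.0, oldest]
    for exc in order:
        anchor += [exc.center_age - exc.duration, exc.center_age,
                   exc.center_age + exc.duration]
    ages = np.unique(np.concatenate([ages, np.array(anchor)]))[::-1]

    slope = (trend_start - trend_end) / oldest  # °C per MY, > 0 when cooling
    ts = trend_end + slope * ages
    for exc in order:
        ts = ts + exc.bump(ages)
    if noise_sd > 0:
        ts = ts + rng.normal(0.0, noise_sd, size=len(ts))

    series = TemperatureSeries(ages=ages, ts=ts, source="synthetic")

    truth = []
    for exc in order:
        net = exc.net_rise_on_flat - slope * exc.duration
        if net > lwp_cfg.min_delta_t and exc.duration >= lwp_cfg.min_duration:
            truth.append(
                WarmingInterval(
                    start_age=exc.center_age + exc.duration,
                    end_age=exc.center_age,
                    delta_t=net,
                    duration=exc.duration,
                )
            )
    return series, truth
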