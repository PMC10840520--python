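"""Locality-paired diversity comparison among co-occurring species.

The design: for k species collected at the same m locality groups, one
sample is retained per (species, group); for every unordered pair of
groups, each species contributes the p-distance between its two chosen
samples. That yields a k x C(m, 2) table of distances whose per-species
row means are the "mean within-species p-distance" compared among species.

Inference is by a locality-stratified permutation test: under the null of
exchangeable species, the k distances of each group-pair stratum are
shuffled among species independently across strata, and the observed
difference of per-species means is compared with the shuffled distribution
(the observed arrangement counts as one replicate). Sampling uncertainty
of each mean is quantified separately by bootstrapping alignment columns.

Because the cells of one species share samples across strata, they are not
independent; the permutation p-values should be read with that caveat in
mind (the stratified shuffle preserves the sharing structure under the
null, but the effective sample size is smaller than C(m, 2)).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distances import DistanceMatrix
from .panel import BarcodePanel, _CODE_MISSING

__all__ = [
    "PairedDesign",
    "PermutationResult",
    "BootstrapResult",
    "build_paired_design",
    "mean_within_species",
    "permutation_test",
    "bootstrap_se",
]


@dataclass
class PairedDesign:
    """k species x C(m, 2) locality-pair table of within-species p-distances.

    ``cells[s, p]`` is the p-distance between species ``species[s]``'s
    chosen samples at the two groups of ``group_pairs[p]``.
    """

    species: list[str]
    groups: list[int]
    chosen: dict[tuple[str, int], str]
    cells: np.ndarray
    group_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        k = len(self.species)
        if not self.group_pairs and self.groups:
            self.group_pairs = list(itertools.combinations(self.groups, 2))
        if self.cells.shape != (k, len(self.group_pairs)):
            raise ValueError(
                f"cells shape {self.cells.shape} != "
                f"({k}, {len(self.group_pairs)})"
            )
        if np.isnan(self.cells).any():
            raise ValueError("design contains undefined distances")
        if ((self.cells < 0) | (self.cells > 1)).any():
            raise ValueError("p-distances must lie in [0, 1]")

    @property
    def n_strata(self) -> int:
        return len(self.group_pairs)

    @classmethod
    def from_matrix(
        cls, species: Sequence[str], cells: np.ndarray
    ) -> "PairedDesign":
        """Build a bare design from a (k, S) cell matrix (tests, simulations)."""
        cells = np.asarray(cells, dtype=float)
        k, S = cells.shape
        # synthesize group labels consistent with S = m(m-1)/2 when possible
        m = int(round((1 + math.sqrt(1 + 8 * S)) / 2))
        if m * (m - 1) // 2 == S:
            groups = list(range(1, m + 1))
            pairs = list(itertools.combinations(groups, 2))
        else:
            groups = []
            pairs = [(i, -i) for i in range(1, S + 1)]
        return cls(
            species=list(species),
            groups=groups,
            chosen={},
            cells=cells,
            group_pairs=pairs,
        )


def build_paired_design(
    panel: BarcodePanel,
    dm: DistanceMatrix,
    species: Sequence[str],
    groups: Sequence[int],
    seed: int | None = None,
    random_choice: bool = False,
) -> PairedDesign:
    """Select one sample per (species, locality group) and fill the design.

    When a (species, group) cell has several candidate samples with
    identical sequences, the lowest seq_id is taken (any choice gives the
    same distances) unless ``random_choice`` requests a seeded draw. If the
    candidates' sequences differ, a warning is emitted and a seeded random
    draw decides.
    """
    rng = np.random.default_rng(seed)
    by_cell: dict[tuple[str, int], list] = {}
    for rec in panel.records:
        if rec.locality_group is None:
            continue
        by_cell.setdefault((rec.species, rec.locality_group), []).append(rec)

    missing = [
        (sp, g) for sp in species for g in groups if (sp, g) not in by_cell
    ]
    if missing:
        raise ValueError(
            "no sample for (species, group) combinations: "
            + ", ".join(f"({sp}, {g})" for sp, g in missing)
        )

    chosen: dict[tuple[str, int], str] = {}
    for sp in species:
        for g in groups:
            cands = sorted(by_cell[(sp, g)], key=lambda r: r.seq_id)
            if len(cands) == 1:
                pick = cands[0]
            elif len({r.sequence for r in cands}) == 1:
                pick = cands[rng.integers(len(cands))] if random_choice else cands[0]
            else:
                warnings.warn(
                    f"multiple non-identical sequences for ({sp}, group {g}); "
                    "picking one at random",
                    stacklevel=2,
                )
                pick = cands[rng.integers(len(cands))]
            chosen[(sp, g)] = pick.seq_id

    pairs = list(itertools.combinations(list(groups), 2))
    cells = np.empty((len(species), len(pairs)))
    for si, sp in enumerate(species):
        for pi, (g1, g2) in enumerate(pairs):
            cells[si, pi] = dm.get(chosen[(sp, g1)], chosen[(sp, g2)])
    if np.isnan(cells).any():
        raise ValueError("design includes an undefined p-distance")
    return PairedDesign(
        species=list(species),
        groups=list(groups),
        chosen=chosen,
        cells=cells,
        group_pairs=pairs,
    )


def mean_within_species(design: PairedDesign) -> dict[str, float]:
    """Arithmetic mean of each species' locality-pair p-distances."""
    means = design.cells.mean(axis=1)
    return {sp: float(m) for sp, m in zip(design.species, means)}


@dataclass(frozen=True)
class PermutationResult:
    """Observed means, pairwise mean differences and permutation p-values."""

    species: tuple[str, ...]
    observed_mean: dict[str, float]
    observed_diff: dict[tuple[str, str], float]
    p_value: dict[tuple[str, str], float]
    n_total: int
    seed: int | None
    exhaustive: bool

    def diff(self, a: str, b: str) -> float:
        if (a, b) in self.observed_diff:
            return self.observed_diff[(a, b)]
        return -self.observed_diff[(b, a)]

    def p(self, a: str, b: str) -> float:
        return self.p_value[(a, b) if (a, b) in self.p_value else (b, a)]


_TIE_EPS = 1e-12


def permutation_test(
    design: PairedDesign,
    n_shuffles: int = 9999,
    seed: int | None = None,
    mode: str = "monte-carlo",
    alternative: str = "two-sided",
    exhaustive_cap: int = 1_000_000,
) -> PermutationResult:
    """Locality-stratified permutation test on differences of species means.

    For every stratum (locality pair) the k species' distances are permuted
    by an independent uniformly random permutation of the species labels.
    The p-value for a species pair counts replicates — including the
    observed arrangement — whose (absolute, if two-sided) difference of
    means is at least the observed one, divided by ``n_shuffles + 1``.

    ``mode="exhaustive"`` enumerates all (k!)^S label assignments instead
    (exact p-values), refusing designs beyond ``exhaustive_cap`` assignments.
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    k, S = design.cells.shape
    if k < 2 or S < 1:
        raise ValueError("need >= 2 species and >= 1 locality-pair stratum")
    V = design.cells  # (k, S)
    obs_means = V.mean(axis=1)
    pairs = list(itertools.combinations(range(k), 2))
    obs_diff = {p: obs_means[p[0]] - obs_means[p[1]] for p in pairs}

    perms = np.array(list(itertools.permutations(range(k))))  # (k!, k)

    if mode == "exhaustive":
        total = len(perms) ** S
        if total > exhaustive_cap:
            raise ValueError(
                f"{total} assignments exceed the exhaustive cap "
                f"({exhaustive_cap}); use mode='monte-carlo'"
            )
        counts = {p: 0 for p in pairs}
        for assign in itertools.product(range(len(perms)), repeat=S):
            idx = perms[list(assign)]  # (S, k): species j gets V[idx[s, j], s]
            means = V[idx.T, np.arange(S)].mean(axis=1)
            for (a, b) in pairs:
                diff = means[a] - means[b]
                ref = obs_diff[(a, b)]
                if alternative == "two-sided":
                    hit = abs(diff) >= abs(ref) - _TIE_EPS
                else:
                    hit = diff >= ref - _TIE_EPS
                counts[(a, b)] += hit
        pvals = {p: counts[p] / total for p in pairs}
        n_total = total
        exhaustive = True
    elif mode == "monte-carlo":
        if n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, len(perms), size=(n_shuffles, S))
        idx = perms[draws]  # (n_shuffles, S, k)
        # species j's replicate values: V[idx[r, s, j], s]
        vals = V.T[np.arange(S)[None, :, None], idx]  # (n_shuffles, S, k)
        null_means = vals.mean(axis=1)  # (n_shuffles, k)
        pvals = {}
        for (a, b) in pairs:
            null = null_means[:, a] - null_means[:, b]
            ref = obs_diff[(a, b)]
            if alternative == "two-sided":
                hits = int((np.abs(null) >= abs(ref) - _TIE_EPS).sum())
            else:
                hits = int((null >= ref - _TIE_EPS).sum())
            pvals[(a, b)] = (hits + 1) / (n_shuffles + 1)
        n_total = n_shuffles + 1
        exhaustive = False
    else:
        raise ValueError(f"unknown mode {mode!r}")

    name = design.species
    return PermutationResult(
        species=tuple(name),
        observed_mean={name[i]: float(obs_means[i]) for i in range(k)},
        observed_diff={(name[a], name[b]): float(obs_diff[(a, b)]) for a, b in pairs},
        p_value={(name[a], name[b]): float(pvals[(a, b)]) for a, b in pairs},
        n_total=n_total,
        seed=seed,
        exhaustive=exhaustive,
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Mean within-species p-distance with its site-bootstrap standard error."""

    species: str
    mean: float
    se: float
    n_replicates: int
    seed: int | None


def bootstrap_se(
    panel: BarcodePanel,
    design: PairedDesign,
    n_replicates: int = 1000,
    seed: int | None = None,
) -> list[BootstrapResult]:
    """Standard error of each species' mean p-distance by site bootstrap.

    Each replicate resamples alignment columns with replacement (one draw
    shared by all sequences), recomputes every design cell's p-distance and
    the per-species means; the SE is the standard deviation (ddof = 1) of
    the replicate means. Replicates in which some pair has zero valid sites
    are dropped with a warning.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if not design.chosen:
        raise ValueError("design carries no chosen samples; build it from a panel")
    k, S = design.cells.shape
    X = panel.encoded()
    pos = {sid: i for i, sid in enumerate(panel.ids)}
    L = X.shape[1]

    ia, ib = [], []
    for sp in design.species:
        for g1, g2 in design.group_pairs:
            ia.append(pos[design.chosen[(sp, g1)]])
            ib.append(pos[design.chosen[(sp, g2)]])
    A, B = X[ia], X[ib]  # (k*S, L)
    valid = (A != _CODE_MISSING) & (B != _CODE_MISSING)
    mism = ((A != B) & valid).astype(np.float64)
    valid = valid.astype(np.float64)

    rng = np.random.default_rng(seed)
    cols = rng.integers(0, L, size=(n_replicates, L))
    # per-replicate column multiplicities -> (L, n_replicates) weight matrix
    W = np.zeros((L, n_replicates))
    for r in range(n_replicates):
        W[:, r] = np.bincount(cols[r], minlength=L)
    n_mism = mism @ W  # (k*S, n_replicates)
    n_valid = valid @ W
    bad = (n_valid == 0).any(axis=0)
    if bad.any():
        warnings.warn(
            f"dropped {int(bad.sum())} bootstrap replicate(s) with zero valid "
            "sites for some pair",
            stacklevel=2,
        )
    keep = ~bad
    with np.errstate(invalid="ignore", divide="ignore"):
        cell_d = (n_mism[:, keep] / n_valid[:, keep]).reshape(k, S, -1)
    rep_means = cell_d.mean(axis=1)  # (k, kept)
    kept = rep_means.shape[1]
    if kept < 2:
        raise RuntimeError("too few bootstrap replicates retained")
    obs_means = design.cells.mean(axis=1)
    return [
        BootstrapResult(
            species=sp,
            mean=float(obs_means[i]),
            se=float(rep_means[i].std(ddof=1)),
            n_replicates=kept,
            seed=seed,
        )
        for i, sp in enumerate(design.species)
    ]
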