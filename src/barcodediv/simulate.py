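"""Synthetic barcode panels with controlled within/between-species divergence.

The generator draws a uniform random root sequence, derives one ancestor
per species by substituting each site with probability ``D`` (a uniform
choice among the three alternative bases, i.e. Jukes–Cantor-like with the
possibility of back-substitution), then draws one sample per (species,
locality group) from the species ancestor as a star phylogeny with
per-species, per-site substitution probability ``q_s``. Two samples of one
species differ at a site iff exactly one lineage mutates, or both do and
land on different bases (probability 2/3 for two independent uniform
choices), so the expected within-species p-distance is exactly

    P(diff) = 2 q (1 - q) + (2/3) q^2 = 2 q (1 - 2 q / 3).

The between-ancestor expectation is the same form in ``D``.

The star phylogeny has no genealogical correlation between samples — real
panels have a coalescent history — so realized distances are more
homogeneous than in nature; see the package docs for what this implies for
test power claims.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import AlignedSeqRecord, BarcodePanel

__all__ = ["SimulationConfig", "simulate_panel", "make_three_species_fixture"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of a k-species x m-group synthetic barcode panel.

    ``within_divergence`` holds one per-site substitution probability q_s
    per species (sample vs species ancestor); ``between_divergence`` D is
    the per-site substitution probability from root to each species
    ancestor. ``missing_fraction`` masks that fraction of trailing sites
    with 'N' in every sample, mimicking 3'-truncated chromatograms.
    """

    n_species: int = 3
    n_groups: int = 14
    alignment_length: int = 658
    within_divergence: Sequence[float] = (0.007, 0.001, 0.0025)
    between_divergence: float = 0.10
    missing_fraction: float = 0.0
    seed: int | None = None
    species_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_groups < 1 or self.alignment_length < 1:
            raise ValueError("counts and alignment length must be positive")
        if len(self.within_divergence) != self.n_species:
            raise ValueError(
                f"within_divergence needs {self.n_species} entries, "
                f"got {len(self.within_divergence)}"
            )
        if any(not 0.0 <= q < 0.25 for q in self.within_divergence):
            raise ValueError("each within_divergence q must satisfy 0 <= q < 0.25")
        if not 0.0 <= self.between_divergence < 0.75:
            raise ValueError("between_divergence D must satisfy 0 <= D < 0.75")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.species_names is not None and len(self.species_names) != self.n_species:
            raise ValueError("species_names length must equal n_species")


def _mutate(seq: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``prob``, uniform among the
    three alternative bases (so a site may revert on a second event)."""
    out = seq.copy()
    hits = np.where(rng.random(seq.size) < prob)[0]
    if hits.size:
        # shift by 1..3 in base space: always lands on a different base
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def simulate_panel(config: SimulationConfig) -> tuple[BarcodePanel, dict]:
    """Simulate a panel and return it with a ground-truth record.

    The truth record holds the config parameters, the species-ancestor
    Hamming fractions, and the realized per-pair Hamming fraction of every
    within-species sample pair (before 'N' masking).
    """
    rng = np.random.default_rng(config.seed)
    k, m, L = config.n_species, config.n_groups, config.alignment_length
    names = (
        list(config.species_names)
        if config.species_names is not None
        else [f"species_{i + 1}" for i in range(k)]
    )

    root = rng.integers(0, 4, size=L, dtype=np.int64)
    ancestors = [_mutate(root, config.between_divergence, rng) for _ in range(k)]
    samples: dict[tuple[int, int], np.ndarray] = {}
    for si in range(k):
        q = config.within_divergence[si]
        for g in range(1, m + 1):
            samples[(si, g)] = _mutate(ancestors[si], q, rng)

    n_mask = int(config.missing_fraction * L)
    records = []
    for si in range(k):
        for g in range(1, m + 1):
            chars = "".join("ACGT"[b] for b in samples[(si, g)])
            if n_mask:
                chars = chars[: L - n_mask] + "N" * n_mask
            records.append(
                AlignedSeqRecord(
                    seq_id=f"s{si + 1:02d}_g{g:02d}",
                    sequence=chars,
                    species=names[si],
                    family="Simfamilia",
                    locality=f"locality_{g}",
                    locality_group=g,
                    country="Synthetica",
                    accession=None,
                )
            )
    panel = BarcodePanel(records)

    ancestor_hamming = {
        f"{names[a]}|{names[b]}": float((ancestors[a] != ancestors[b]).mean())
        for a, b in itertools.combinations(range(k), 2)
    }
    within_hamming = {
        names[si]: {
            f"g{g1}|g{g2}": float((samples[(si, g1)] != samples[(si, g2)]).mean())
            for g1, g2 in itertools.combinations(range(1, m + 1), 2)
        }
        for si in range(k)
    }
    truth = {
        "n_species": k,
        "n_groups": m,
        "alignment_length": L,
        "within_divergence": list(config.within_divergence),
        "between_divergence": config.between_divergence,
        "missing_fraction": config.missing_fraction,
        "seed": config.seed,
        "species_names": names,
        "ancestor_hamming": ancestor_hamming,
        "within_hamming": within_hamming,
    }
    return panel, truth


def make_three_species_fixture(seed: int | None = None) -> tuple[BarcodePanel, dict]:
    """Desk-scale stand-in for a 3-species x 14-locality barcode subset.

    Within-species substitution probabilities q = (0.007, 0.001, 0.0025)
    put the three realized mean within-species p-distances near 1.3%, 0.2%
    and 0.5% — one clearly diverse species, one nearly invariant, one
    intermediate — over 658 aligned sites, with ancestors ~17% apart.
    """
    config = SimulationConfig(
        n_species=3,
        n_groups=14,
        alignment_length=658,
        within_divergence=(0.007, 0.001, 0.0025),
        between_divergence=0.10,
        missing_fraction=0.0,
        seed=seed,
    )
    return simulate_panel(config)
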