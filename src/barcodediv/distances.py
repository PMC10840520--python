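"""Uncorrected p-distances and species-level divergence summaries.

The p-distance between two aligned sequences is the proportion of differing
sites among the sites where *both* sequences carry a determinate base
(A, C, G or T). Gaps, ``N`` and IUPAC ambiguity codes are treated as
indeterminate. Under the default *pairwise deletion*, indeterminate sites
are excluded per pair; under *complete deletion*, any column with an
indeterminate character in any panel sequence is excluded globally.

No substitution-model correction is applied: these are the raw divergences
conventionally used for barcode-gap analysis and species delimitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import _ENCODE_TABLE, _CODE_MISSING, BarcodePanel

__all__ = [
    "DistanceMatrix",
    "SpeciesSummary",
    "p_distance",
    "distance_matrix",
    "matrix_from_codes",
    "species_summaries",
    "threshold_flags",
]


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_TABLE[raw]
    if (codes == 255).any():
        pos = int(np.argmax(codes == 255)) + 1
        raise ValueError(f"illegal character {seq[pos - 1]!r} at position {pos}")
    return codes


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected p-distance between two aligned sequences.

    Returns ``(distance, valid_sites)`` where ``valid_sites`` counts the
    positions at which both sequences have a determinate base. When no site
    qualifies the distance is undefined and returned as ``nan`` with
    ``valid_sites = 0``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences must have equal length ({len(seq_a)} != {len(seq_b)})"
        )
    a, b = _encode(seq_a), _encode(seq_b)
    valid = (a != _CODE_MISSING) & (b != _CODE_MISSING)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return float("nan"), 0
    mismatches = int(((a != b) & valid).sum())
    return mismatches / n_valid, n_valid


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix with per-pair valid-site counts.

    Entries with zero jointly determinate sites are ``nan`` (undefined);
    downstream consumers that need a complete matrix must reject them.
    """

    ids: list[str]
    d: np.ndarray
    valid_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.valid_sites.shape != (n, n):
            raise ValueError("matrix shapes do not match the id list")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_complete(self) -> bool:
        return not np.isnan(self.d).any()

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, j in zip(*np.where(np.isnan(self.d))):
            if i < j:
                out.append((self.ids[i], self.ids[j]))
        return out

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.d[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append(
                    {
                        "id_a": self.ids[i],
                        "id_b": self.ids[j],
                        "p_distance": self.d[i, j],
                        "valid_sites": int(self.valid_sites[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "p_distance", "valid_sites"])

    def write_square_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="seq_id")

    def write_long_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance matrix (relaxed names, tab-separated)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, name in enumerate(self.ids):
                row = "\t".join(f"{x:.8f}" for x in self.d[i])
                fh.write(f"{name}\t{row}\n")


def matrix_from_codes(X: np.ndarray, ids: list[str]) -> DistanceMatrix:
    """Pairwise-deletion distance matrix from an (n, L) code matrix."""
    n = X.shape[0]
    determinate = X != _CODE_MISSING
    d = np.zeros((n, n))
    vs = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(vs, determinate.sum(axis=1))
    for i in range(n):
        valid = determinate[i] & determinate[i + 1 :]
        mism = ((X[i] != X[i + 1 :]) & valid).sum(axis=1)
        nv = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(nv > 0, mism / np.maximum(nv, 1), np.nan)
        d[i, i + 1 :] = dist
        d[i + 1 :, i] = dist
        vs[i, i + 1 :] = nv
        vs[i + 1 :, i] = nv
    return DistanceMatrix(list(ids), d, vs)


def distance_matrix(
    panel: BarcodePanel, deletion: str = "pairwise"
) -> DistanceMatrix:
    """All-pairs p-distance matrix for a panel.

    ``deletion`` selects how indeterminate sites are handled: ``"pairwise"``
    (default) drops them per sequence pair, ``"complete"`` drops every
    alignment column containing any indeterminate character before
    computing distances.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    X = panel.encoded()
    if deletion == "complete":
        keep = ~(X == _CODE_MISSING).any(axis=0)
        X = X[:, keep]

    dm = matrix_from_codes(X, list(panel.ids))
    if not dm.is_complete():
        pairs = dm.undefined_pairs()
        warnings.warn(
            f"{len(pairs)} sequence pair(s) share no determinate site; "
            f"their distances are undefined (first: {pairs[0]})",
            stacklevel=2,
        )
    return dm


@dataclass(frozen=True)
class SpeciesSummary:
    """Intraspecific divergence range and nearest-neighbour distance.

    ``intra_*`` fields are ``None`` for singleton species. The nearest
    neighbour is the other species with the smallest arithmetic mean of all
    between-species pairwise distances; ties break lexicographically.
    """

    species: str
    n_samples: int
    intra_min: float | None
    intra_max: float | None
    intra_mean: float | None
    nearest_neighbour: str
    nn_avg_distance: float


def _species_blocks(
    dm: DistanceMatrix, species_of: Mapping[str, str]
) -> dict[str, np.ndarray]:
    blocks: dict[str, list[int]] = {}
    for idx, seq_id in enumerate(dm.ids):
        if seq_id not in species_of:
            raise KeyError(f"no species label for sequence {seq_id!r}")
        blocks.setdefault(species_of[seq_id], []).append(idx)
    return {sp: np.asarray(ix) for sp, ix in blocks.items()}


def species_summaries(
    dm: DistanceMatrix, species_of: Mapping[str, str]
) -> list[SpeciesSummary]:
    """Per-species intraspecific min/max/mean and nearest-neighbour distance."""
    if not dm.is_complete():
        raise ValueError(
            "distance matrix has undefined entries; summaries need completeness"
        )
    blocks = _species_blocks(dm, species_of)
    names = sorted(blocks)
    if len(names) < 2:
        raise ValueError("species summaries need at least 2 species")

    out = []
    for sp in names:
        ix = blocks[sp]
        if len(ix) >= 2:
            sub = dm.d[np.ix_(ix, ix)]
            vals = sub[np.triu_indices(len(ix), 1)]
            intra = (float(vals.min()), float(vals.max()), float(vals.mean()))
        else:
            intra = (None, None, None)
        best_name, best_mean = None, np.inf
        for other in names:
            if other == sp:
                continue
            cross = dm.d[np.ix_(ix, blocks[other])]
            m = float(cross.mean())
            if m < best_mean or (m == best_mean and other < best_name):
                best_name, best_mean = other, m
        out.append(
            SpeciesSummary(
                species=sp,
                n_samples=len(ix),
                intra_min=intra[0],
                intra_max=intra[1],
                intra_mean=intra[2],
                nearest_neighbour=best_name,
                nn_avg_distance=best_mean,
            )
        )
    return out


def threshold_flags(
    dm: DistanceMatrix,
    species_of: Mapping[str, str],
    threshold: float = 0.02,
) -> list[tuple[str, float, bool]]:
    """Flag species whose maximum intraspecific distance exceeds a cutoff.

    The default 2% cutoff is the conventional heuristic for insect barcode
    species delimitation; species represented by a single sample are skipped.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if not dm.is_complete():
        raise ValueError("distance matrix has undefined entries")
    blocks = _species_blocks(dm, species_of)
    out = []
    for sp in sorted(blocks):
        ix = blocks[sp]
        if len(ix) < 2:
            continue
        sub = dm.d[np.ix_(ix, ix)]
        mx = float(sub[np.triu_indices(len(ix), 1)].max())
        out.append((sp, mx, mx > threshold))
    return out
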