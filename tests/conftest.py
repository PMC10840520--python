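from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from barcodediv import (
    AlignedSeqRecord,
    BarcodePanel,
    distance_matrix,
    make_three_species_fixture,
    write_panel,
)

DATA_DIR = Path(__file__).parent / "data"


def make_panel(seqs: dict[str, str], species: dict[str, str] | None = None,
               groups: dict[str, int] | None = None) -> BarcodePanel:
    """Hand-rolled panel builder for small explicit test cases."""
    records = []
    for sid, seq in seqs.items():
        records.append(
            AlignedSeqRecord(
                seq_id=sid,
                sequence=seq,
                species=(species or {}).get(sid, "sp_" + sid),
                locality_group=(groups or {}).get(sid),
            )
        )
    return BarcodePanel(records)


def random_panel(rng: np.random.Generator, n: int, L: int,
                 missing_prob: float = 0.1) -> BarcodePanel:
    """Random panel with sprinkled gaps/N/ambiguity for oracle comparisons."""
    alphabet = np.array(list("ACGT-NRY"))
    probs = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
    probs[4:] = missing_prob * 4 / 4
    probs /= probs.sum()
    records = []
    for i in range(n):
        chars = rng.choice(alphabet, size=L, p=probs)
        records.append(
            AlignedSeqRecord(
                seq_id=f"r{i:03d}",
                sequence="".join(chars),
                species=f"sp{i % 4}",
            )
        )
    return BarcodePanel(records)


@pytest.fixture(scope="session")
def checklist_path() -> Path:
    return DATA_DIR / "species_checklist.tsv"


@pytest.fixture(scope="session")
def three_species_panel():
    panel, truth = make_three_species_fixture(seed=20231)
    return panel, truth


@pytest.fixture(scope="session")
def three_species_design(three_species_panel):
    from barcodediv import build_paired_design

    panel, _ = three_species_panel
    dm = distance_matrix(panel)
    species = sorted(set(panel.species))
    design = build_paired_design(panel, dm, species, list(range(1, 15)), seed=0)
    return panel, dm, design


@pytest.fixture()
def panel_files(tmp_path):
    """Write a small mixed panel to disk; returns (fasta, metadata, panel)."""
    panel = make_panel(
        {
            "a1": "ACGTACGTAC",
            "a2": "ACGTACGTAT",
            "b1": "AC-GTNACGT",
        },
        species={"a1": "Alpha one", "a2": "Alpha one", "b1": "Beta two"},
        groups={"a1": 1, "a2": 2, "b1": 1},
    )
    fasta = tmp_path / "panel.fasta"
    meta = tmp_path / "panel.tsv"
    write_panel(panel, fasta, meta)
    return fasta, meta, panel
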