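"""Shared fixtures: a tiny hand-built genome and simulator-backed inputs.

All fixture data is generated programmatically; nothing is read from
disk except through tmp_path round trips inside individual tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from plantelements.genome_windows import GeneModel
from plantelements.race_simulator import make_toy_genome
from plantelements.transcript_metrics import CassetteModel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_genome():
    """3 kb single-chromosome genome with one gene per strand."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    genome = {"chr1": seq}
    models = {
        # plus-strand gene: exons 1500..1700 / 2001..2300 -> intron 1701..2000
        "gplus": GeneModel("gplus", "chr1", "+", ((1500, 1700), (2001, 2300))),
        # minus-strand gene: transcription right-to-left, TSS at 1500
        "gminus": GeneModel("gminus", "chr1", "-", ((1300, 1500), (900, 1100))),
    }
    return genome, models


@pytest.fixture(scope="session")
def toy():
    """Deterministic annotated toy genome with a planted TATAAA at -30."""
    return make_toy_genome(
        seed=7, n_genes=25, chrom_length=180_000,
        planted_motif="TATAAA", motif_offset=-30, penetrance=0.8,
    )


@pytest.fixture(scope="session")
def cassette():
    """Single-intron reporter cassette mirroring the characterization
    layout: promoter 5'-most base = 1, leader intron at (511, 814)."""
    return CassetteModel(
        cassette_id="cassette1",
        length=3400,
        parts=[("promoter_leader", 1, 510), ("intron", 511, 814),
               ("cds", 815, 2900), ("utr3", 2901, 3400)],
        intended_tss=481,
        intended_junctions=[(511, 814)],
        intended_polya_sites=[3126, 3186],
    )
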