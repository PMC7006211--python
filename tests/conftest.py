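import pytest

from gutatlas.simulate import (
    ARCHETYPES,
    FamilySpec,
    SyntheticSpec,
    simulate_dataset,
)

EIGHT_ARCHETYPE_WEIGHTS = {a: 1.0 / len(ARCHETYPES) for a in ARCHETYPES}

FAMILY_SPECS = (
    FamilySpec("CYP", "p450", 5, (250, 400), panel_size=4),
    FamilySpec("SP", "transporter", 5, (300, 420), n_tm=4, panel_size=4),
    FamilySpec("AAAP", "transporter", 4, (280, 400), n_tm=3, panel_size=4),
)


def family_dataset(seed: int, n_decoys: int = 70, planted: bool = True):
    """Small catalog with planted families among >= 5x decoys."""
    spec = SyntheticSpec(
        n_genes=n_decoys,
        planted_families=FAMILY_SPECS if planted else (),
        contaminant_frac=0.0,
        contained_frac=0.0,
        isoform_rate=0.0,
        seed=seed,
    )
    return simulate_dataset(spec)


def gene_level(sequences: dict[str, str]) -> dict[str, str]:
    """Collapse accession_i1 keys to gene-level ids (single-isoform sets)."""
    return {acc.rsplit("_i", 1)[0]: s for acc, s in sequences.items()}


@pytest.fixture(scope="session")
def small_dataset():
    """General-purpose synthetic dataset shared across test modules."""
    return simulate_dataset(SyntheticSpec(n_genes=300, seed=42))
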