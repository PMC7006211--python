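"""Synthetic midgut-atlas data with known planted structure.

The generator emulates the statistical shape of a de-novo midgut
transcriptome study: Trinity-style gene/isoform accessions, a minority of
bacterial-like contaminant genes, redundant records that are exact
substrings of longer ones, planted gene families carrying either a
cytochrome-P450 heme-ligand motif or a bundle of transmembrane helices,
and a five-tissue (M1-M4 + carcass), replicated TPM matrix in which each
gene follows one of eight archetypal expression patterns along the gut
(four single-compartment peaks, a monotone anterior-to-posterior
increase and decrease, an anterior plateau and a mid-gut peak) or a flat
background profile.

Every generated gene is covered by a :class:`PlantedTruth` record so
downstream stages can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gutatlas.io import TISSUES

# ---------------------------------------------------------------------------
# archetypes

#: Mean TPM profiles over (M1, M2, M3, M4, carcass).
ARCHETYPE_PROFILES: dict[str, tuple[float, ...]] = {
    # single-compartment transcripts are below the 1-TPM presence
    # threshold elsewhere, so compartment-overlap partitions show the
    # mixture of shared and section-specific expression seen in guts
    "M1_specific": (120.0, 0.6, 0.6, 0.6, 0.6),
    "M2_specific": (0.6, 120.0, 0.6, 0.6, 0.6),
    "M3_specific": (0.6, 0.6, 120.0, 0.6, 0.6),
    "M4_specific": (0.6, 0.6, 0.6, 120.0, 0.6),
    "increasing": (5.0, 25.0, 60.0, 120.0, 8.0),
    "decreasing": (120.0, 60.0, 25.0, 5.0, 8.0),
    "anterior": (80.0, 80.0, 80.0, 0.6, 8.0),
    "mid_peak": (8.0, 80.0, 80.0, 8.0, 8.0),
    "flat": (20.0, 20.0, 20.0, 20.0, 20.0),
}

ARCHETYPES = tuple(a for a in ARCHETYPE_PROFILES if a != "flat")

DEFAULT_ARCHETYPE_WEIGHTS: dict[str, float] = {
    **{a: 0.06 for a in ARCHETYPES},
    "flat": 0.52,
}

# contaminant genes mirror the symbiont signal: mostly M4-peaked, some
# anterior-restricted, the rest background
_CONTAMINANT_ARCHETYPES = (("M4_specific", 0.55), ("anterior", 0.15), ("flat", 0.30))

# amino-acid background frequencies (SwissProt-like, renormalised)
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array([
    0.083, 0.014, 0.055, 0.067, 0.039, 0.071, 0.023, 0.059, 0.058, 0.097,
    0.024, 0.040, 0.047, 0.039, 0.055, 0.066, 0.053, 0.069, 0.011, 0.029,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

HYDROPHOBIC = "LIVFA"
POLAR = "DEKNQRSTGH"

P450_MOTIF_RE = re.compile(r"F..G.[RH].C.G")
#: concrete instance of the P450 heme-ligand pattern F-x-x-G-x-[RH]-x-C-x-G
_P450_MOTIF_INSTANCE = "FSAGPRNCIG"


# ---------------------------------------------------------------------------
# specs and truth


@dataclass(frozen=True)
class FamilySpec:
    """One planted gene family.

    ``kind`` is ``"p450"`` (members carry the heme-ligand motif) or
    ``"transporter"`` (members carry ``n_tm`` hydrophobic helices of at
    least 19 residues).
    """

    name: str
    kind: str
    n_members: int
    length_range: tuple[int, int]
    n_tm: int = 0
    panel_size: int = 6  # members per reference species

    def __post_init__(self) -> None:
        if self.kind not in ("p450", "transporter"):
            raise ValueError(f"unknown family kind: {self.kind!r}")
        lo, hi = self.length_range
        if lo > hi or lo < 60:
            raise ValueError(f"bad length_range for family {self.name}")
        if self.kind == "transporter":
            if self.n_tm < 1:
                raise ValueError("transporter family needs n_tm >= 1")
            # k helices of 21 plus linkers must fit the stated range
            if self.n_tm * 21 + (self.n_tm + 1) * 15 > hi:
                raise ValueError(
                    f"template length exceeds sequence length for {self.name}"
                )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_genes: int = 1000
    isoform_rate: float = 0.3
    contaminant_frac: float = 0.09
    contained_frac: float = 0.05
    archetype_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_WEIGHTS)
    )
    noise_cv: float = 0.2
    replicates: int = 4
    planted_families: tuple[FamilySpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        for name in ("isoform_rate", "contaminant_frac", "contained_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        w = dict(self.archetype_weights)
        unknown = set(w) - set(ARCHETYPE_PROFILES)
        if unknown:
            raise ValueError(f"archetype_weights has unknown archetypes: {unknown}")
        if any(v < 0 for v in w.values()):
            raise ValueError("archetype_weights must be non-negative")
        total = sum(w.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"archetype_weights must sum to 1, got {total}")


@dataclass
class PlantedTruth:
    """Ground-truth labels for every generated gene."""

    archetype: dict[str, str] = field(default_factory=dict)
    family: dict[str, str | None] = field(default_factory=dict)
    contaminant: dict[str, bool] = field(default_factory=dict)
    enriched_terms: dict[str, list[str]] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return list(self.archetype)


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus the planted truth."""

    spec: SyntheticSpec
    sequences: dict[str, str]  # accession (with isoform suffix) -> protein
    taxon_annotation: pd.DataFrame  # gene_id, taxon_group, e_value
    term_annotation: pd.DataFrame  # gene_id, term_id, term_kind
    expression: pd.DataFrame  # gene_id x tissue_replicate TPM
    panels: dict[str, "FamilyPanelData"]
    truth: PlantedTruth


@dataclass
class FamilyPanelData:
    """Reference panel for one family: members of two reference species."""

    name: str
    kind: str
    members: dict[str, str]  # accession -> sequence (both species pooled)


# ---------------------------------------------------------------------------
# helpers


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, spec_seed])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length, p=_AA_FREQ))


def _gene_id(i: int) -> str:
    return f"TRINITY_DN{1000 + i}_c0_g1"


def _weighted_choice(rng: np.random.Generator, items: Sequence[tuple[str, float]]) -> str:
    names = [n for n, _ in items]
    p = np.array([w for _, w in items], dtype=float)
    return str(rng.choice(names, p=p / p.sum()))


def signature_term(archetype: str) -> str:
    """Pfam-style signature term planted into one archetype's genes."""
    return f"PF9{ARCHETYPES.index(archetype):04d}"


# ---------------------------------------------------------------------------
# generators


def gen_unigene_catalog(
    spec: SyntheticSpec,
) -> tuple[dict[str, str], pd.DataFrame, PlantedTruth]:
    """Generate the unigene catalog: sequences, taxon annotation, truth.

    Returns an accession->sequence mapping (accessions carry isoform
    suffixes; a fraction of genes have a second, shorter isoform), a
    taxon-annotation table in which contaminant genes have a bacterial
    best hit with e-value < 1e-5, and the planted-truth record.
    """
    rng = _rng(spec.seed, 11)
    truth = PlantedTruth()
    seqs: dict[str, str] = {}
    taxon_rows: list[tuple[str, str, float]] = []

    arch_names = list(spec.archetype_weights)
    arch_p = np.array([spec.archetype_weights[a] for a in arch_names], dtype=float)
    arch_p = arch_p / arch_p.sum()

    primary_seqs: list[str] = []
    for i in range(spec.n_genes):
        gene = _gene_id(i)
        contaminant = bool(rng.random() < spec.contaminant_frac)
        if contaminant:
            archetype = _weighted_choice(rng, _CONTAMINANT_ARCHETYPES)
        else:
            archetype = str(rng.choice(arch_names, p=arch_p))

        if primary_seqs and rng.random() < spec.contained_frac:
            # exact substring of an earlier gene, to exercise containment dedup
            donor = primary_seqs[int(rng.integers(len(primary_seqs)))]
            sub_len = max(60, int(len(donor) * 0.6))
            start = int(rng.integers(0, len(donor) - sub_len + 1))
            seq = donor[start : start + sub_len]
        else:
            seq = _random_protein(rng, int(rng.integers(150, 501)))
        primary_seqs.append(seq)

        seqs[f"{gene}_i1"] = seq
        if rng.random() < spec.isoform_rate and len(seq) > 80:
            # shorter isoform: N-terminal truncation, distinct length
            cut = int(rng.integers(20, len(seq) // 2))
            seqs[f"{gene}_i2"] = seq[cut:]

        truth.archetype[gene] = archetype
        truth.family[gene] = None
        truth.contaminant[gene] = contaminant
        if contaminant:
            e = 10.0 ** float(rng.uniform(-40, -6))  # always < 1e-5
            taxon_rows.append((gene, "bacteria", e))
        elif rng.random() < 0.5:
            taxon_rows.append(
                (gene, "arthropoda", 10.0 ** float(rng.uniform(-60, -6)))
            )

    taxon = pd.DataFrame(taxon_rows, columns=["gene_id", "taxon_group", "e_value"])
    for arch in ARCHETYPES:
        truth.enriched_terms[arch] = [signature_term(arch)]
    return seqs, taxon, truth


def gen_expression(
    truth: PlantedTruth,
    replicates: int = 4,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate TPM matrix for every gene in ``truth``.

    Each gene's mean profile is its archetype profile scaled by a
    gene-specific lognormal amplitude; replicate values are that mean
    times multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (mean exactly the archetype mean when ``noise_cv=0``).
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    rng = _rng(seed, 23)
    genes = truth.genes()
    unknown = {a for a in truth.archetype.values() if a not in ARCHETYPE_PROFILES}
    if unknown:
        raise ValueError(f"unknown archetype label(s): {sorted(unknown)}")

    profiles = np.array([ARCHETYPE_PROFILES[truth.archetype[g]] for g in genes])
    amp = rng.lognormal(mean=0.0, sigma=0.5, size=len(genes))
    means = profiles * amp[:, None]  # genes x 5 tissues

    n_cols = len(TISSUES) * replicates
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        noise = rng.lognormal(
            mean=-(sigma**2) / 2.0, sigma=sigma, size=(len(genes), n_cols)
        )
    else:
        noise = np.ones((len(genes), n_cols))

    cols = [f"{t}_{r}" for t in TISSUES for r in range(1, replicates + 1)]
    rep_means = np.repeat(means, replicates, axis=1)
    values = rep_means * noise
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols)


def gen_term_annotation(truth: PlantedTruth, seed: int = 0) -> pd.DataFrame:
    """Term-annotation table with planted per-archetype signature terms.

    Genes of each non-flat archetype carry that archetype's signature
    Pfam-style term with probability 0.6 (background genes with
    probability 0.02), so archetype gene groups are genuinely enriched.
    A set of GO-style background terms is sprinkled uniformly.
    """
    rng = _rng(seed, 37)
    rows: list[tuple[str, str, str]] = []
    genes = truth.genes()
    for g in genes:
        arch = truth.archetype[g]
        for a in ARCHETYPES:
            term = signature_term(a)
            p = 0.6 if a == arch else 0.02
            if rng.random() < p:
                rows.append((g, term, "PFAM"))
    for t in range(20):
        term = f"GO:00800{t:02d}"
        mask = rng.random(len(genes)) < 0.05
        for g, hit in zip(genes, mask):
            if hit:
                rows.append((g, term, "GO"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_kind"])


# -- family sequences -------------------------------------------------------


def _mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    tm_mask: np.ndarray,
    protected: np.ndarray,
) -> str:
    """Point-mutate ``seq``; helix positions stay hydrophobic, protected
    (motif) positions are untouched."""
    chars = list(seq)
    hits = rng.random(len(chars)) < rate
    for i in np.nonzero(hits)[0]:
        if protected[i]:
            continue
        pool = HYDROPHOBIC if tm_mask[i] else POLAR
        chars[i] = pool[int(rng.integers(len(pool)))]
    return "".join(chars)


def _family_ancestor(
    fam: FamilySpec, rng: np.random.Generator
) -> tuple[str, np.ndarray, np.ndarray]:
    """Build the family ancestor plus its helix and motif masks."""
    lo, hi = fam.length_range
    target = (lo + hi) // 2
    if fam.kind == "transporter":
        k = fam.n_tm
        helix_len = 21
        linker_total = target - k * helix_len
        base_linker = linker_total // (k + 1)
        parts: list[str] = []
        tm_flags: list[bool] = []
        for j in range(k):
            ln = base_linker if j > 0 else linker_total - base_linker * k
            linker = _random_protein(rng, max(15, ln))
            # keep linkers decisively hydrophilic so helix calls are clean
            linker = "".join(
                c if c not in HYDROPHOBIC else POLAR[int(rng.integers(len(POLAR)))]
                for c in linker
            )
            parts.append(linker)
            tm_flags.extend([False] * len(linker))
            helix = "".join(
                HYDROPHOBIC[int(rng.integers(len(HYDROPHOBIC)))]
                for _ in range(helix_len)
            )
            parts.append(helix)
            tm_flags.extend([True] * helix_len)
        tail = _random_protein(rng, max(15, base_linker))
        tail = "".join(
            c if c not in HYDROPHOBIC else POLAR[int(rng.integers(len(POLAR)))]
            for c in tail
        )
        parts.append(tail)
        tm_flags.extend([False] * len(tail))
        seq = "".join(parts)
        tm_mask = np.array(tm_flags)
        protected = np.zeros(len(seq), dtype=bool)
    else:  # p450-like: motif planted in the C-terminal third
        seq = _random_protein(rng, target)
        pos = int(target * 0.75)
        seq = seq[:pos] + _P450_MOTIF_INSTANCE + seq[pos + len(_P450_MOTIF_INSTANCE):]
        tm_mask = np.zeros(len(seq), dtype=bool)
        protected = np.zeros(len(seq), dtype=bool)
        protected[pos : pos + len(_P450_MOTIF_INSTANCE)] = True
    return seq, tm_mask, protected


def _derive_member(
    ancestor: str,
    tm_mask: np.ndarray,
    protected: np.ndarray,
    rate: float,
    max_trim: int,
    rng: np.random.Generator,
) -> str:
    """Mutated copy of the ancestor with a small C-terminal trim."""
    seq = _mutate(ancestor, rate, rng, tm_mask, protected)
    trim = int(rng.integers(0, max_trim + 1))
    return seq[: len(seq) - trim] if trim else seq


def gen_family_sequences(
    spec: SyntheticSpec,
) -> tuple[dict[str, str], dict[str, FamilyPanelData], PlantedTruth]:
    """Planted family members plus two-reference-species panels.

    Members of one family descend from a common ancestor (point
    substitutions at 10%, helix positions stay hydrophobic, the P450
    motif is conserved); reference-panel members are more diverged (22%)
    copies of the same ancestor, so reciprocal homology search finds the
    planted members while unrelated decoys stay below threshold.
    """
    rng = _rng(spec.seed, 53)
    additions: dict[str, str] = {}
    panels: dict[str, FamilyPanelData] = {}
    truth = PlantedTruth()

    gene_counter = 900_000  # planted accessions live in their own DN range
    for fam in spec.planted_families:
        ancestor, tm_mask, protected = _family_ancestor(fam, rng)
        members: dict[str, str] = {}
        for _ in range(fam.n_members):
            gene = f"TRINITY_DN{gene_counter}_c0_g1"
            gene_counter += 1
            seq = _derive_member(ancestor, tm_mask, protected, 0.10, 4, rng)
            additions[f"{gene}_i1"] = seq
            members[gene] = seq
            if fam.kind == "transporter":
                archetype = str(rng.choice(["M4_specific", "increasing"]))
            else:
                archetype = str(rng.choice(["M1_specific", "anterior", "decreasing"]))
            truth.archetype[gene] = archetype
            truth.family[gene] = fam.name
            truth.contaminant[gene] = False

        panel_members: dict[str, str] = {}
        for species in ("human", "fly"):
            for j in range(fam.panel_size):
                acc = f"{species}_{fam.name}_{j + 1}"
                # each species contributes one full-length member, so the
                # panel length range always brackets the family's members
                trim = 0 if j == 0 else 12
                panel_members[acc] = _derive_member(
                    ancestor, tm_mask, protected, 0.22, trim, rng
                )
        panels[fam.name] = FamilyPanelData(fam.name, fam.kind, panel_members)

    return additions, panels, truth


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a complete, mutually consistent synthetic dataset."""
    seqs, taxon, truth = gen_unigene_catalog(spec)
    fam_seqs, panels, fam_truth = gen_family_sequences(spec)
    seqs = {**seqs, **fam_seqs}
    truth.archetype.update(fam_truth.archetype)
    truth.family.update(fam_truth.family)
    truth.contaminant.update(fam_truth.contaminant)

    expression = gen_expression(
        truth, replicates=spec.replicates, noise_cv=spec.noise_cv, seed=spec.seed
    )
    terms = gen_term_annotation(truth, seed=spec.seed)
    return SyntheticDataset(
        spec=spec,
        sequences=seqs,
        taxon_annotation=taxon,
        term_annotation=terms,
        expression=expression,
        panels=panels,
        truth=truth,
    )


def spec_from_mapping(cfg: Mapping) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a plain mapping (YAML config)."""
    cfg = dict(cfg)
    fams = tuple(
        FamilySpec(
            name=f["name"],
            kind=f["kind"],
            n_members=int(f["n_members"]),
            length_range=tuple(f["length_range"]),
            n_tm=int(f.get("n_tm", 0)),
            panel_size=int(f.get("panel_size", 6)),
        )
        for f in cfg.pop("planted_families", [])
    )
    known = {f.name for f in dataclasses.fields(SyntheticSpec)}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown synthetic-spec keys: {sorted(unknown)}")
    if "archetype_weights" in cfg:
        cfg["archetype_weights"] = dict(cfg["archetype_weights"])
    return SyntheticSpec(planted_families=fams, **cfg)
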