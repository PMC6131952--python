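"""Synthetic mock-community study generator.

Generates complete studies (SV count tables, sample metadata, qPCR plates,
and a latent-truth record) with the statistical structure that 16S rRNA
amplicon reproducibility analyses assume:

* a defined multi-strain mock community profiled repeatedly across many
  sequencing runs, with a multiplicative log-normal run-to-run batch
  effect and Dirichlet within-run replicate noise;
* repeat stool specimens from a single donor, whose between-specimen
  (biological) variation exceeds the run effect;
* negative controls that contain nothing but a reagent-contaminant
  profile and yield few reads;
* a sequential dilution series of the mock community in which the share
  of contaminant reads grows as input biomass falls, with a small
  systematic over-dilution bias per pipetting step;
* qPCR copy-number measurements with multiplicative log-normal error and
  a plasmid standard curve.

The generative chain for one library is::

    run composition  --Dirichlet(c * p)-->  replicate composition
        --mix w = L/(L+copies)-->  contaminated composition
        --Multinomial(template molecules)-->  template pool
        --Multinomial(read depth)-->  SV counts

The finite-template bottleneck (template molecules = (copies + L) x
template volume) is what couples compositional noise to input biomass:
dilute libraries are resampled through a small pool of molecules, which
inflates replicate-to-replicate distances and depresses observed alpha
diversity exactly as low-input amplicon libraries behave.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import FeatureTable, join_lineage, make_metadata

__all__ = [
    "MockCommunitySpec",
    "RunDesign",
    "StudyDesign",
    "NoiseModel",
    "SyntheticStudy",
    "mock_community",
    "stool_community",
    "full_study_design",
    "dilution_design",
    "sample_run_composition",
    "mix_contamination",
    "draw_counts",
    "simulate_dilution_series",
    "simulate_study",
    "SIM_CURVE_SLOPE",
    "SIM_CURVE_INTERCEPT",
]

# Standard curve used when synthesising qPCR plates: perfect amplification
# efficiency (slope = -1/log10(2)) with a 40-cycle intercept.
SIM_CURVE_SLOPE = -3.3219
SIM_CURVE_INTERCEPT = 40.0

# ---------------------------------------------------------------------------
# Built-in communities
# ---------------------------------------------------------------------------

def _lineage(phylum, klass, order, family, genus, species):
    return join_lineage(["Bacteria", phylum, klass, order, family, genus, species])


#: 33 clinically relevant strains forming the default whole-cell mock
#: community.  Several genera appear more than once so taxonomic
#: collapsing is non-trivial.
MOCK_STRAINS: tuple[tuple[str, str], ...] = tuple(
    (f"sv_mock_{i+1:02d}", _lineage(*tax))
    for i, tax in enumerate([
        ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Citrobacter", "freundii"),
        ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia", "coli"),
        ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Klebsiella", "pneumoniae"),
        ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Enterobacter", "cloacae"),
        ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Morganellaceae", "Proteus", "mirabilis"),
        ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Yersiniaceae", "Serratia", "marcescens"),
        ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Salmonella", "enterica"),
        ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Shigella", "flexneri"),
        ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Haemophilus", "influenzae"),
        ("Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", "Neisseria", "meningitidis"),
        ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae", "Enterococcus", "faecalis"),
        ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae", "Enterococcus", "faecium"),
        ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", "pneumoniae"),
        ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", "pyogenes"),
        ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", "agalactiae"),
        ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus", "aureus"),
        ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus", "epidermidis"),
        ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", "acidophilus"),
        ("Firmicutes", "Bacilli", "Bacillales", "Listeriaceae", "Listeria", "monocytogenes"),
        ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus", "subtilis"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Peptostreptococcaceae", "Clostridioides", "difficile"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Lachnoclostridium", "clostridioforme"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Dorea", "formicigenerans"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Blautia", "producta"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Mediterraneibacter", "gnavus"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae", "Faecalibacterium", "prausnitzii"),
        ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", "fragilis"),
        ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", "thetaiotaomicron"),
        ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella", "melaninogenica"),
        ("Fusobacteriota", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium", "nucleatum"),
        ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Veillonella", "parvula"),
        ("Actinobacteriota", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", "longum"),
        ("Campylobacterota", "Campylobacteria", "Campylobacterales", "Campylobacteraceae", "Campylobacter", "jejuni"),
    ])
)

#: Typical extraction-kit / reagent contaminant genera; these SVs never
#: occur in any true community.
CONTAMINANT_STRAINS: tuple[tuple[str, str], ...] = tuple(
    (f"sv_contam_{i+1:02d}", _lineage(*tax))
    for i, tax in enumerate([
        ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas", "fluorescens"),
        ("Proteobacteria", "Gammaproteobacteria", "Moraxellales", "Moraxellaceae", "Moraxella", "osloensis"),
        ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Ralstonia", "pickettii"),
        ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas", "paucimobilis"),
        ("Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Methylobacteriaceae", "Methylobacterium", "radiotolerans"),
        ("Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Nitrobacteraceae", "Bradyrhizobium", "japonicum"),
        ("Proteobacteria", "Gammaproteobacteria", "Moraxellales", "Moraxellaceae", "Acinetobacter", "lwoffii"),
        ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Burkholderia", "cepacia"),
    ])
)

#: Gut commensals for the repeat-stool-specimen arm.
STOOL_TAXA: tuple[tuple[str, str], ...] = tuple(
    (f"sv_stool_{i+1:02d}", _lineage(*tax))
    for i, tax in enumerate([
        ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", "vulgatus"),
        ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", "uniformis"),
        ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella", "copri"),
        ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes", "putredinis"),
        ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Tannerellaceae", "Parabacteroides", "distasonis"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae", "Faecalibacterium", "prausnitzii"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae", "Ruminococcus", "bromii"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Roseburia", "intestinalis"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Anaerostipes", "hadrus"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Coprococcus", "comes"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Blautia", "obeum"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Fusicatenibacter", "saccharivorans"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Clostridiaceae", "Clostridium", "leptum"),
        ("Firmicutes", "Negativicutes", "Acidaminococcales", "Acidaminococcaceae", "Phascolarctobacterium", "faecium"),
        ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Dialister", "invisus"),
        ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", "salivarius"),
        ("Actinobacteriota", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", "adolescentis"),
        ("Actinobacteriota", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Collinsella", "aerofaciens"),
        ("Verrucomicrobiota", "Verrucomicrobiae", "Verrucomicrobiales", "Akkermansiaceae", "Akkermansia", "muciniphila"),
        ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia", "fergusonii"),
        ("Firmicutes", "Clostridia", "Eubacteriales", "Eubacteriaceae", "Eubacterium", "rectale"),
        ("Desulfobacterota", "Desulfovibrionia", "Desulfovibrionales", "Desulfovibrionaceae", "Bilophila", "wadsworthia"),
    ])
)


def geometric_proportions(n: int, decay: float = 0.7) -> np.ndarray:
    """Normalised geometric series ``decay**k``; a staggered composition."""
    if not 0 < decay <= 1:
        raise ValueError("decay must be in (0, 1]")
    w = decay ** np.arange(n, dtype=float)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MockCommunitySpec:
    """A defined community: taxa, true proportions, and stock biomass.

    ``stock_copies_per_ul`` is the 16S gene copy concentration of the
    undiluted stock.
    """

    taxa: tuple[tuple[str, str], ...]
    true_proportions: np.ndarray
    stock_copies_per_ul: float

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple((str(a), str(b)) for a, b in self.taxa))
        p = np.asarray(self.true_proportions, dtype=float)
        object.__setattr__(self, "true_proportions", p)
        if len(self.taxa) < 2:
            raise ValueError("a community needs at least 2 taxa")
        ids = [t[0] for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("taxon ids must be unique")
        if p.shape != (len(self.taxa),):
            raise ValueError("proportions length must match taxa")
        if (p < 0).any():
            raise ValueError("proportions must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions must sum to 1 (got {p.sum()!r})")
        if not self.stock_copies_per_ul > 0:
            raise ValueError("stock_copies_per_ul must be positive")

    @property
    def taxon_ids(self) -> list[str]:
        return [t[0] for t in self.taxa]


def mock_community(n_taxa: int = 33, proportions: str = "uniform",
                   decay: float = 0.7,
                   stock_copies_per_ul: float = 7520.0) -> MockCommunitySpec:
    """Built-in mock community.

    ``proportions='uniform'`` gives equal strain proportions (the default);
    ``'staggered'`` gives a geometric abundance gradient, useful when an
    abundance-variability relationship is being studied.  The default stock
    concentration of 7520 copies/uL places the 1:80 dilution at ~94
    copies/uL, the practical lower limit for robust profiling.
    """
    if not 2 <= n_taxa <= len(MOCK_STRAINS):
        raise ValueError(f"n_taxa must be in [2, {len(MOCK_STRAINS)}]")
    taxa = MOCK_STRAINS[:n_taxa]
    if proportions == "uniform":
        p = np.full(n_taxa, 1.0 / n_taxa)
    elif proportions == "staggered":
        p = geometric_proportions(n_taxa, decay)
    else:
        raise ValueError("proportions must be 'uniform' or 'staggered'")
    p = p / p.sum()
    return MockCommunitySpec(taxa=taxa, true_proportions=p,
                             stock_copies_per_ul=stock_copies_per_ul)


def stool_community(stock_copies_per_ul: float = 2.0e5) -> MockCommunitySpec:
    """Built-in high-biomass stool community (staggered proportions)."""
    p = geometric_proportions(len(STOOL_TAXA), 0.82)
    return MockCommunitySpec(taxa=STOOL_TAXA, true_proportions=p,
                             stock_copies_per_ul=stock_copies_per_ul)


@dataclass(frozen=True)
class RunDesign:
    run_id: str
    n_mock: int = 0
    n_stool: int = 0
    n_negative: int = 0

    def __post_init__(self):
        if min(self.n_mock, self.n_stool, self.n_negative) < 0:
            raise ValueError("sample counts must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a synthetic study.

    ``depth_distribution`` is (median reads, log-SD) of a log-normal read
    depth per library, truncated at 1; negatives get their own, much
    shallower, ``negative_depth_distribution``.  An empty
    ``dilution_levels`` disables the dilution-series run.
    """

    runs: tuple[RunDesign, ...] = ()
    dilution_levels: tuple[float, ...] = ()
    replicates_per_level: int = 10
    dilution_run_id: str = "run18"
    depth_distribution: tuple[float, float] = (30000.0, 0.35)
    negative_depth_distribution: tuple[float, float] = (1000.0, 0.6)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "runs", tuple(self.runs))
        lv = tuple(float(x) for x in self.dilution_levels)
        object.__setattr__(self, "dilution_levels", lv)
        if any(d < 1 for d in lv):
            raise ValueError("dilution factors must be >= 1")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("dilution factors must be strictly increasing")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be positive")
        for mean, sd in (self.depth_distribution, self.negative_depth_distribution):
            if mean <= 0 or sd < 0:
                raise ValueError("depth distribution needs positive mean, sd >= 0")


#: The ten dilution factors of the prospective series, plus stock.
DILUTION_FACTORS = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 500.0, 1000.0)

# Per-run sample layout of the 19-run retrospective study.  Only the totals
# (218 mock incl. the 110-library dilution run, 29 stool over 3 runs, 222
# negatives, one run with a single mock) are constrained; the per-run
# split is a plausible allocation under them.
_FULL_MOCK = {1: 5, 2: 7, 3: 9, 4: 6, 5: 9, 6: 4, 7: 8, 8: 3, 9: 6, 10: 6,
                11: 7, 12: 5, 13: 8, 14: 1, 15: 8, 16: 4, 17: 3, 19: 9}
_FULL_STOOL = {2: 8, 9: 15, 16: 6}
_FULL_NEG = {1: 5, 2: 7, 3: 12, 4: 1, 5: 3, 6: 7, 7: 5, 8: 6, 9: 7, 10: 11,
               11: 38, 12: 10, 13: 33, 14: 10, 15: 1, 16: 27, 17: 13, 18: 24, 19: 2}


def full_study_design(seed: int = 0) -> StudyDesign:
    """19-run study layout: 218 mock + 29 stool + 222 negative libraries.

    Run 18 is the prospective dilution run (11 levels x 10 replicates =
    110 libraries, all typed as mock); run 14 carries a single mock.
    """
    runs = []
    for r in range(1, 20):
        if r == 18:
            runs.append(RunDesign("run18", n_mock=0, n_stool=0,
                                  n_negative=_FULL_NEG.get(r, 0)))
        else:
            runs.append(RunDesign(f"run{r:02d}", n_mock=_FULL_MOCK.get(r, 0),
                                  n_stool=_FULL_STOOL.get(r, 0),
                                  n_negative=_FULL_NEG.get(r, 0)))
    return StudyDesign(runs=tuple(runs), dilution_levels=DILUTION_FACTORS,
                       replicates_per_level=10, dilution_run_id="run18",
                       seed=seed)


def dilution_design(seed: int = 0, replicates_per_level: int = 10,
                    levels: tuple[float, ...] = DILUTION_FACTORS) -> StudyDesign:
    """A single dilution-series run with no other samples."""
    return StudyDesign(runs=(), dilution_levels=levels,
                       replicates_per_level=replicates_per_level,
                       dilution_run_id="run18", seed=seed)


@dataclass(frozen=True)
class NoiseModel:
    """All stochastic knobs of the generator.

    * ``run_effect_sd`` - SD of the per-taxon log-proportion perturbation
      shared by all libraries of a run (the batch effect).
    * ``replicate_concentration`` - Dirichlet concentration ``c`` for
      within-run replicate noise (alpha = c * run composition); larger is
      tighter.
    * ``specimen_effect_sd`` - log-proportion SD between stool specimens
      of the same donor (biological variation).
    * ``contaminant_profile`` / ``contaminant_load`` - reagent contaminant
      composition and its effective concentration L (copies/uL), constant
      per study; a library with c copies/uL receives contaminant weight
      w = L / (L + c).
    * ``qpcr_cv`` - log-normal sigma (ln scale) on measured copy numbers.
    * ``overdilution_bias`` - systematic per-step over-dilution multiplier
      (>= 1); step k of the sequential series truly holds
      stock / (factor_k * bias**k) copies/uL.
    * ``template_volume_ul`` - template volume per reaction; together with
      copies/uL it sets the finite-template bottleneck size.
    """

    run_effect_sd: float = 0.30
    replicate_concentration: float = 800.0
    specimen_effect_sd: float = 0.80
    contaminant_taxa: tuple[tuple[str, str], ...] = CONTAMINANT_STRAINS
    contaminant_profile: np.ndarray = field(
        default_factory=lambda: geometric_proportions(len(CONTAMINANT_STRAINS), 0.55))
    contaminant_load: float = 2.0
    qpcr_cv: float = 0.10
    overdilution_bias: float = 1.05
    template_volume_ul: float = 5.0

    def __post_init__(self):
        q = np.asarray(self.contaminant_profile, dtype=float)
        object.__setattr__(self, "contaminant_profile", q)
        object.__setattr__(self, "contaminant_taxa",
                           tuple((str(a), str(b)) for a, b in self.contaminant_taxa))
        if self.run_effect_sd < 0 or self.specimen_effect_sd < 0 or self.qpcr_cv < 0:
            raise ValueError("SDs must be >= 0")
        if self.replicate_concentration <= 0:
            raise ValueError("replicate_concentration must be positive")
        if self.contaminant_load < 0:
            raise ValueError("contaminant_load must be >= 0")
        if self.overdilution_bias < 1:
            raise ValueError("overdilution_bias must be >= 1")
        if q.shape != (len(self.contaminant_taxa),):
            raise ValueError("contaminant profile length must match contaminant taxa")
        if (q < 0).any() or abs(q.sum() - 1.0) > 1e-12:
            raise ValueError("contaminant_profile must be a probability vector")
        if self.template_volume_ul <= 0:
            raise ValueError("template_volume_ul must be positive")


@dataclass
class SyntheticStudy:
    """A complete generated study plus its latent truth."""

    counts: FeatureTable
    metadata: pd.DataFrame
    qpcr: pd.DataFrame          # sample_id-indexed: ct, copies_per_ul
    qpcr_wells: pd.DataFrame    # long: sample_id, well, ct
    standards: pd.DataFrame     # copies_per_reaction, ct
    truth: dict

    def __post_init__(self):
        missing = self.metadata.index.difference(self.counts.sample_ids)
        if len(missing):
            raise ValueError(f"metadata samples missing from counts: {list(missing)[:5]}")
        missing = set(self.counts.sample_ids) - set(self.truth["samples"])
        if missing:
            raise ValueError(f"truth missing samples: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def sample_run_composition(spec: MockCommunitySpec, noise: NoiseModel,
                           rng: np.random.Generator) -> np.ndarray:
    """Perturb the true proportions by a shared-run log-normal batch effect."""
    p = spec.true_proportions
    z = rng.normal(0.0, noise.run_effect_sd, size=p.size)
    q = p * np.exp(z)
    return q / q.sum()


def _perturb(p: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    q = p * np.exp(rng.normal(0.0, sd, size=p.size))
    return q / q.sum()


def mix_contamination(sample_proportions: np.ndarray, sample_copies_per_ul: float,
                      noise: NoiseModel) -> np.ndarray:
    """Two-source constant-load contamination mixture.

    Returns a probability vector over (community SVs ++ contaminant SVs)
    with contaminant weight ``w = L / (L + copies)``; w = 1 at zero input
    (a negative control) and w -> 0 at high biomass.
    """
    if sample_copies_per_ul < 0:
        raise ValueError("copies must be >= 0")
    p = np.asarray(sample_proportions, dtype=float)
    L = noise.contaminant_load
    w = 0.0 if L == 0 else L / (L + sample_copies_per_ul)
    return np.concatenate(((1.0 - w) * p, w * noise.contaminant_profile))


def draw_counts(proportions: np.ndarray, depth: int,
                rng: np.random.Generator) -> np.ndarray:
    """Multinomial read sampling at a fixed depth."""
    p = np.asarray(proportions, dtype=float)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
        raise ValueError("proportions must form a probability vector")
    return rng.multinomial(depth, p / p.sum())


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

def _sample_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # Deterministic per-sample sub-streams split from the study seed.
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, index]))


def _draw_depth(dist: tuple[float, float], rng: np.random.Generator) -> int:
    median, sd = dist
    return max(1, int(round(math.exp(rng.normal(math.log(median), sd)))))


class _StudyBuilder:
    """Accumulates libraries over a fixed SV universe."""

    def __init__(self, community_taxa, noise: NoiseModel, design: StudyDesign):
        self.noise = noise
        self.design = design
        self.community_ids = [t[0] for t in community_taxa]
        self.contam_ids = [t[0] for t in noise.contaminant_taxa]
        overlap = set(self.community_ids) & set(self.contam_ids)
        if overlap:
            raise ValueError(f"contaminant SVs overlap community SVs: {sorted(overlap)[:5]}")
        self.sv_ids = self.community_ids + self.contam_ids
        self.taxonomy = pd.Series(
            dict(list(community_taxa) + list(noise.contaminant_taxa))
        ).loc[self.sv_ids]
        self.columns: dict[str, np.ndarray] = {}
        self.meta_rows: list[dict] = []
        self.truth: dict[str, dict] = {}
        self.qpcr_rows: list[dict] = []
        self.well_rows: list[dict] = []
        self._index = 0

    def embed(self, ids: list[str], p: np.ndarray) -> np.ndarray:
        """Place a composition over a taxon subset into community coordinates."""
        full = np.zeros(len(self.community_ids))
        pos = [self.community_ids.index(i) for i in ids]
        full[pos] = p
        return full

    def add_library(self, sample_id: str, community_p: np.ndarray, copies: float,
                    run_id: str, sample_type: str, specimen_id=None,
                    dilution_factor=np.nan, depth_dist=None, measure_qpcr=False):
        noise = self.noise
        rng = _sample_rng(self.design.seed, 1, self._index)
        self._index += 1

        # within-run replicate (extraction/PCR) noise on the community part
        rep = np.asarray(community_p, dtype=float)
        support = rep > 0
        if support.any() and copies > 0:
            alpha = noise.replicate_concentration * rep[support]
            rep = np.zeros_like(rep)
            rep[support] = rng.dirichlet(alpha)

        mixed = mix_contamination(rep, copies, noise)

        # finite-template bottleneck: resample through the molecule pool
        n_template = max(1, int(round((copies + noise.contaminant_load)
                                      * noise.template_volume_ul)))
        template = rng.multinomial(n_template, mixed)
        pool = template / template.sum()

        depth = _draw_depth(depth_dist or self.design.depth_distribution, rng)
        counts = draw_counts(pool, depth, rng)

        self.columns[sample_id] = counts
        self.meta_rows.append(dict(sample_id=sample_id, run_id=run_id,
                                   sample_type=sample_type, specimen_id=specimen_id,
                                   dilution_factor=dilution_factor))
        w = (0.0 if noise.contaminant_load == 0
             else noise.contaminant_load / (noise.contaminant_load + copies))
        self.truth[sample_id] = dict(
            composition=mixed.tolist(), true_copies_per_ul=float(copies),
            contaminant_weight=float(w), n_template=int(n_template),
            depth=int(depth))

        if measure_qpcr:
            self._measure(sample_id, copies, rng)

    def _measure(self, sample_id: str, copies: float, rng: np.random.Generator):
        noise = self.noise
        if copies > 0:
            measured = copies * math.exp(rng.normal(0.0, noise.qpcr_cv))
            per_rxn = measured * noise.template_volume_ul
            ct_true = SIM_CURVE_INTERCEPT + SIM_CURVE_SLOPE * math.log10(per_rxn)
            cts = ct_true + rng.normal(0.0, 0.05, size=3)
            mean_ct = float(np.mean(cts))
        else:
            measured, cts, mean_ct = 0.0, [np.nan] * 3, np.nan
        self.qpcr_rows.append(dict(sample_id=sample_id, ct=mean_ct,
                                   copies_per_ul=measured))
        for k, ct in enumerate(cts):
            self.well_rows.append(dict(sample_id=sample_id, well=f"w{k+1}",
                                       ct=float(ct) if np.isfinite(ct) else np.nan))

    def build(self) -> SyntheticStudy:
        counts = pd.DataFrame(self.columns, index=pd.Index(self.sv_ids, name="sv_id"),
                              dtype=np.int64)
        metadata = make_metadata(pd.DataFrame(self.meta_rows))
        qpcr = pd.DataFrame(self.qpcr_rows).set_index("sample_id") if self.qpcr_rows \
            else pd.DataFrame(columns=["ct", "copies_per_ul"])
        wells = pd.DataFrame(self.well_rows) if self.well_rows \
            else pd.DataFrame(columns=["sample_id", "well", "ct"])
        standards = _standard_plate(self.design.seed)
        truth = dict(samples=self.truth, sv_ids=list(self.sv_ids),
                     contaminant_sv_ids=list(self.contam_ids))
        return SyntheticStudy(counts=FeatureTable(counts, self.taxonomy),
                              metadata=metadata, qpcr=qpcr, qpcr_wells=wells,
                              standards=standards, truth=truth)


def _standard_plate(seed: int) -> pd.DataFrame:
    """Triplicate plasmid standards at 0, 1e2 ... 1e7 copies/reaction."""
    rng = _sample_rng(seed, 4, 0)
    rows = []
    for c in [0.0] + [10.0 ** k for k in range(2, 8)]:
        for k in range(3):
            if c > 0:
                ct = SIM_CURVE_INTERCEPT + SIM_CURVE_SLOPE * math.log10(c) \
                    + rng.normal(0.0, 0.05)
            else:
                ct = np.nan  # no-template wells stay undetermined
            rows.append(dict(copies_per_reaction=c, well=f"w{k+1}", ct=ct))
    return pd.DataFrame(rows)


def _add_dilution_run(builder: _StudyBuilder, spec: MockCommunitySpec,
                      design: StudyDesign, noise: NoiseModel):
    levels = sorted(design.dilution_levels)
    run_id = design.dilution_run_id
    run_rng = _sample_rng(design.seed, 0, 10_000)
    run_p = builder.embed(spec.taxon_ids,
                          sample_run_composition(spec, noise, run_rng))
    for k, factor in enumerate(levels):
        copies = spec.stock_copies_per_ul / (factor * noise.overdilution_bias ** k)
        for rep in range(design.replicates_per_level):
            sid = f"{run_id}_d{int(factor):04d}_{rep+1:02d}"
            builder.add_library(sid, run_p, copies, run_id=run_id,
                                sample_type="mock", dilution_factor=factor,
                                measure_qpcr=True)


def simulate_dilution_series(spec: MockCommunitySpec | None = None,
                             design: StudyDesign | None = None,
                             noise: NoiseModel | None = None,
                             seed: int | None = None) -> SyntheticStudy:
    """Simulate the prospective sequential dilution run alone.

    At level index k with factor d the library truly contains
    ``stock / (d * overdilution_bias**k)`` copies/uL; qPCR measures that
    with multiplicative log-normal error.  The default design (stock plus
    ten factors, 10 replicates each) yields 110 libraries.
    """
    spec = spec or mock_community()
    design = design or dilution_design()
    noise = noise or NoiseModel()
    if seed is not None:
        design = replace(design, seed=seed)
    if not design.dilution_levels:
        raise ValueError("design has no dilution levels")
    builder = _StudyBuilder(spec.taxa, noise, design)
    _add_dilution_run(builder, spec, design, noise)
    return builder.build()


def simulate_study(spec: MockCommunitySpec | None = None,
                   design: StudyDesign | None = None,
                   noise: NoiseModel | None = None,
                   stool_spec: MockCommunitySpec | None = None,
                   n_stool_specimens: int = 3,
                   seed: int | None = None) -> SyntheticStudy:
    """Simulate a complete multi-run study.

    Every run draws one batch-effect composition per profiled community;
    mock libraries replicate it with Dirichlet noise, stool libraries come
    from donor specimens perturbed by ``specimen_effect_sd``, negative
    controls carry zero input (pure contamination at low depth), and the
    dilution run is appended when the design defines one.  Fixing the
    design seed makes the output byte-identical across calls.
    """
    spec = spec or mock_community()
    design = design if design is not None else full_study_design()
    noise = noise or NoiseModel()
    stool_spec = stool_spec or stool_community()
    if seed is not None:
        design = replace(design, seed=seed)

    any_stool = any(r.n_stool > 0 for r in design.runs)
    community_taxa = list(spec.taxa) + (list(stool_spec.taxa) if any_stool else [])
    builder = _StudyBuilder(community_taxa, noise, design)

    # donor stool specimens (latent biological compositions)
    specimens = {}
    if any_stool:
        for s in range(n_stool_specimens):
            srng = _sample_rng(design.seed, 2, s)
            specimens[f"s{s+1}"] = _perturb(stool_spec.true_proportions,
                                            noise.specimen_effect_sd, srng)

    for r_idx, run in enumerate(design.runs):
        run_rng = _sample_rng(design.seed, 0, r_idx)
        mock_p = builder.embed(spec.taxon_ids,
                               sample_run_composition(spec, noise, run_rng))
        # one batch-effect draw per run for the stool community too
        stool_eps = run_rng.normal(0.0, noise.run_effect_sd,
                                   size=len(stool_spec.taxa)) if any_stool else None

        for i in range(run.n_mock):
            builder.add_library(f"{run.run_id}_mock_{i+1:02d}", mock_p,
                                spec.stock_copies_per_ul, run_id=run.run_id,
                                sample_type="mock", dilution_factor=1.0)
        for i in range(run.n_stool):
            spec_id = sorted(specimens)[i % len(specimens)]
            base = specimens[spec_id] * np.exp(stool_eps)
            base = base / base.sum()
            builder.add_library(f"{run.run_id}_stool_{spec_id}_{i+1:02d}",
                                builder.embed(stool_spec.taxon_ids, base),
                                stool_spec.stock_copies_per_ul, run_id=run.run_id,
                                sample_type="stool", specimen_id=spec_id,
                                dilution_factor=1.0)
        for i in range(run.n_negative):
            builder.add_library(f"{run.run_id}_neg_{i+1:02d}",
                                np.zeros(len(builder.community_ids)), 0.0,
                                run_id=run.run_id, sample_type="negative",
                                depth_dist=design.negative_depth_distribution)

    if design.dilution_levels:
        _add_dilution_run(builder, spec, design, noise)

    return builder.build()
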