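"""Synthetic multi-species genotyping panels with planted ground truth.

The generator emulates the structure of a grapevine breeding/diversity
panel hybridized on a SNP array: a cultivated V. vinifera cluster, a
sylvestris-like cluster and several divergent wild-species clusters
(Balding–Nichols per-population allele-frequency draws around a common
ancestral frequency), a multi-generation pedigree with Mendelian
transmission, per-call genotyping error, missingness elevated in wild
accessions, somatic-variant duplicate pairs differing at a fixed handful
of markers, maternally inherited plastid haplotypes, and trait loci with
deterministic genotype -> phenotype maps (flower sex, seed development,
OIV-225 berry colour, muscat taste, a methoxypyrazine marker haplotype).

Every planted fact (relationships, duplicates, chlorotypes, failing
markers, trait rules) is returned in a truth record so downstream stages
can be validated by parameter recovery. Random-number streams are split
per concern (markers, founders, transmission, traits, plastid, noisy
markers, error, duplicates, missingness, candidate VCF) so toggling one
process does not shift the others.

Two distinct noise processes are modelled:

- the panel-wide genotyping error is a symmetric single-step perturbation
  (hom -> het; het -> either hom with equal probability), the smallest
  model producing both opposing homozygotes and heterozygous mismatches;
- planted *failing* markers (the targets of Mendelian marker filtering)
  model probeset cluster collapse: a fraction of their calls is wrong and
  homozygous — a het falls into a random hom cluster, a hom into the
  opposite one — the characteristic miscall pattern of a degraded
  probeset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import GenotypeMatrix
from .traits import TraitRule

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationConfig:
    """One founder population: a species-like cluster.

    ``fst`` is the Balding–Nichols divergence parameter from the common
    ancestral pool; ``is_wild`` adds the wild-species missingness boost.
    """

    name: str
    fst: float
    n_founders: int
    species: str = ""
    is_wild: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ConfigError(f"population {self.name!r}: fst must be in (0, 1)")
        if self.n_founders < 1:
            raise ConfigError(f"population {self.name!r}: n_founders must be >= 1")


@dataclass(frozen=True)
class CrossConfig:
    """One cross: ``n_offspring`` full siblings of mother x father.

    Parents may be founders or offspring of earlier crosses (multi-
    generation pedigrees); referencing a sample that does not exist yet is
    a configuration error.
    """

    mother: str
    father: str
    n_offspring: int
    offspring_prefix: str = "G1"

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise ConfigError("n_offspring must be >= 1")


@dataclass(frozen=True)
class CandidateVcfConfig:
    """Volume knobs of the synthetic candidate-variant VCF.

    Counts are per (species, chromosome) cell except ``n_proximal_pairs``,
    which plants pairs of otherwise-clean variants 20 nt apart.
    """

    n_samples: int = 12
    n_clean_per_cell: int = 330
    n_low_qual: int = 10
    n_indel: int = 10
    n_multiallelic: int = 10
    n_low_depth: int = 10
    n_high_missing: int = 10
    n_at_cg: int = 10
    n_proximal_pairs: int = 5
    clean_qual: float = 200.0
    low_qual: float = 50.0
    depth: int = 20
    low_depth: int = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Full panel-simulation parameterization (defaults = study conditions).

    The default panel is a 120-sample, ~5,000-marker breeding panel: 42
    founders in five populations, 76 offspring over two generations (152
    parent-offspring duos, 76 trios — the relationship density of a real
    breeding parental panel), two somatic-variant duplicate pairs at 6
    discordant markers, 0.5% per-call genotyping error, 3% base
    missingness (+3% in wild species), 100 failing markers with 10% of
    calls miscalled, six plastid SNPs (one monomorphic) over three
    chlorotypes, and fully penetrant trait loci.
    """

    chromosomes: tuple[str, ...] = tuple(f"chr{i:02d}" for i in range(1, 20))
    plastid_chromosome: str = "chrCP"
    n_markers_per_chromosome: int = 262
    n_plastid_markers: int = 6
    populations: tuple[PopulationConfig, ...] = (
        PopulationConfig("vinifera", 0.05, 30, species="V. vinifera"),
        PopulationConfig(
            "sylvestris", 0.15, 6, species="V. vinifera ssp. sylvestris"
        ),
        PopulationConfig("riparia", 0.35, 2, species="V. riparia", is_wild=True),
        PopulationConfig("amurensis", 0.40, 2, species="V. amurensis", is_wild=True),
        PopulationConfig(
            "rotundifolia", 0.45, 2, species="M. rotundifolia", is_wild=True
        ),
    )
    crosses: tuple[CrossConfig, ...] = ()
    pedigree_depth: int = 2
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    genotyping_error_rate: float = 0.005
    missing_rate_base: float = 0.03
    missing_rate_wild_boost: float = 0.03
    n_low_call_rate_samples: int = 1
    low_call_rate_target: float = 0.80
    n_duplicate_pairs: int = 2
    duplicate_discordance: int = 6
    n_noisy_markers: int = 100
    noisy_replacement_rate: float = 0.10
    n_chlorotypes: int = 3
    chlorotype_freqs: tuple[float, ...] = (0.5, 0.3, 0.2)
    plant_traits: bool = True
    #: planted recombination cases per faulty sex marker, alternating
    #: between the female-sterility and male-sterility marker sets
    sex_recombination: tuple[int, ...] = (7, 1)
    candidate_vcf: CandidateVcfConfig = CandidateVcfConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "genotyping_error_rate",
            "missing_rate_base",
            "missing_rate_wild_boost",
            "noisy_replacement_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.duplicate_discordance < 0:
            raise ConfigError("duplicate_discordance must be >= 0")
        if self.n_chlorotypes > len(self.chlorotype_freqs):
            raise ConfigError("chlorotype_freqs shorter than n_chlorotypes")

    @property
    def n_autosomal_markers(self) -> int:
        n = len(self.chromosomes) * self.n_markers_per_chromosome
        if self.plant_traits:
            n += 9 + 1 + 1 + 1 + 11  # sex, colour, seed, muscat, mpz
        return n


def default_crosses() -> tuple[CrossConfig, ...]:
    """The default two-generation breeding pedigree (76 offspring).

    Fourteen founder couples with five offspring each, one half-sib cross
    re-using the mother of couple 1 and the father of couple 2, one
    second-generation cross between offspring of different couples
    (grandparent and avuncular pairs), and two interspecific (hybrid)
    crosses. With both parents of every offspring on the panel this gives
    152 parent-offspring duos and 76 trios among 120 samples — the
    relationship density of a breeding parental panel.
    """
    crosses: list[CrossConfig] = []
    for c in range(14):
        crosses.append(
            CrossConfig(
                mother=f"VIN_{2 * c + 1:03d}",
                father=f"VIN_{2 * c + 2:03d}",
                n_offspring=5,
                offspring_prefix="G1",
            )
        )
    # half-sib cross: shares the mother of couple 1 and the father of couple 2
    crosses.append(CrossConfig("VIN_001", "VIN_004", 2, offspring_prefix="G1"))
    crosses.append(CrossConfig("G1_001", "G1_006", 2, offspring_prefix="G2"))
    crosses.append(CrossConfig("VIN_029", "RIP_001", 1, offspring_prefix="HYB"))
    crosses.append(CrossConfig("VIN_030", "AMU_001", 1, offspring_prefix="HYB"))
    return tuple(crosses)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-conditions configuration with the standard pedigree."""
    kwargs = {"crosses": default_crosses(), "seed": seed}
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# Truth record
# ---------------------------------------------------------------------------


@dataclass
class TraitTruth:
    """Planted trait architecture: rules plus the facts they should recover."""

    color_rule: TraitRule | None = None
    seed_rule: TraitRule | None = None
    muscat_rule: TraitRule | None = None
    female_sterility_rules: tuple[TraitRule, ...] = ()
    male_sterility_rules: tuple[TraitRule, ...] = ()
    haplotype_rules: tuple[TraitRule, ...] = ()
    color_collapse: dict = field(default_factory=dict)
    #: rule_id -> planted carrier sample ids for each haplotype rule
    haplotype_groups: dict = field(default_factory=dict)
    #: (marker_id, n planted recombinant samples) for faulty sex markers
    recombinant_sex_markers: tuple[tuple[str, int], ...] = ()

    @property
    def penetrant_rules(self) -> list[TraitRule]:
        return [r for r in (self.color_rule, self.seed_rule, self.muscat_rule) if r]


@dataclass
class PanelTruth:
    """Everything planted into a simulated panel."""

    po_pairs: tuple[tuple[str, str], ...]
    trios: tuple[tuple[str, str, str], ...]
    duplicate_pairs: tuple[tuple[str, str], ...]
    chlorotypes: dict[str, str]
    plastid_marker_ids: tuple[str, ...]
    noisy_markers: tuple[str, ...]
    clean_markers: tuple[str, ...]
    low_call_rate_samples: tuple[str, ...]
    traits: TraitTruth = field(default_factory=TraitTruth)

    def to_json(self, path: str | Path) -> Path:
        def rule_dict(r: TraitRule | None):
            if r is None:
                return None
            d = asdict(r)
            d["applicability"] = sorted(r.applicability) if r.applicability else None
            return d

        payload = {
            "po_pairs": [list(p) for p in self.po_pairs],
            "trios": [list(t) for t in self.trios],
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            "chlorotypes": self.chlorotypes,
            "plastid_marker_ids": list(self.plastid_marker_ids),
            "noisy_markers": list(self.noisy_markers),
            "clean_markers": list(self.clean_markers),
            "low_call_rate_samples": list(self.low_call_rate_samples),
            "traits": {
                "color_rule": rule_dict(self.traits.color_rule),
                "seed_rule": rule_dict(self.traits.seed_rule),
                "muscat_rule": rule_dict(self.traits.muscat_rule),
                "female_sterility_rules": [
                    rule_dict(r) for r in self.traits.female_sterility_rules
                ],
                "male_sterility_rules": [
                    rule_dict(r) for r in self.traits.male_sterility_rules
                ],
                "haplotype_rules": [
                    rule_dict(r) for r in self.traits.haplotype_rules
                ],
                "color_collapse": {
                    str(k): v for k, v in self.traits.color_collapse.items()
                },
                "haplotype_groups": self.traits.haplotype_groups,
                "recombinant_sex_markers": [
                    list(t) for t in self.traits.recombinant_sex_markers
                ],
            },
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


@dataclass
class PanelSimulation:
    gm: GenotypeMatrix
    samples: pd.DataFrame
    markers: pd.DataFrame
    truth: PanelTruth

    @property
    def pedigree(self) -> pd.DataFrame:
        return self.samples[["sample_id", "mother_id", "father_id"]].copy()

    @property
    def nuclear_gm(self) -> GenotypeMatrix:
        """The panel without plastid markers.

        Plastid loci are haploid and maternally inherited, so they violate
        biparental transmission by construction (a father-offspring duo
        with different chlorotypes shows opposing homozygotes there);
        duo/trio Mendelian statistics are meant to run on this subset.
        """
        plastid = list(self.markers.loc[self.markers["is_plastid"], "marker_id"])
        return self.gm.drop_markers(plastid)


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

_STREAMS = (
    "markers",
    "founders",
    "transmission",
    "traits",
    "plastid",
    "noisy",
    "error",
    "duplicates",
    "missingness",
    "vcf",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _gamete(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele count per marker (0 or 1 copies of B)."""
    out = (genotype == 2).astype(np.int8)
    het = genotype == 1
    out[het] = rng.integers(0, 2, int(het.sum()), dtype=np.int8)
    return out


def _single_step_error(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric single-step perturbation: hom->het, het->either hom."""
    if rate <= 0:
        return codes
    out = codes.copy()
    hit = rng.random(out.shape) < rate
    het = out == 1
    out[hit & ~het] = 1
    flip = hit & het
    out[flip] = rng.integers(0, 2, int(flip.sum()), dtype=np.int8) * 2
    return out


def simulate_panel(cfg: SimulationConfig) -> PanelSimulation:
    """Generate a genotyped panel with metadata and planted truth.

    The order of operations matters and is fixed: founder draws, Mendelian
    transmission, trait-locus overwrites, plastid haplotypes, failing-marker
    corruption, panel-wide genotyping error, duplicate cloning (with exactly
    ``duplicate_discordance`` planted discordant calls), then missingness.
    Plastid and trait-candidate markers are exempt from the error and
    missingness processes (see the module docstring and methods note).
    """
    rngs = _rngs(cfg.seed)

    # ---- marker table ------------------------------------------------
    marker_rows: list[dict] = []
    rng_m = rngs["markers"]
    for chrom in cfg.chromosomes:
        pos = np.sort(
            rng_m.choice(
                np.arange(10_000, 25_000_000), size=cfg.n_markers_per_chromosome, replace=False
            )
        )
        for i, p in enumerate(pos):
            marker_rows.append(
                {
                    "marker_id": f"AX_{chrom}_{i:04d}",
                    "chromosome": chrom,
                    "position": int(p),
                    "source": "resequencing",
                    "species_of_origin": "",
                    "is_plastid": False,
                    "trait_annotation": "",
                }
            )
    n_regular = len(marker_rows)

    trait_defs: list[tuple[str, str, str]] = []  # (marker_id, chromosome, annotation)
    if cfg.plant_traits:
        trait_defs += [(f"TRAIT_SEX_{i:02d}", "chr02", "flower_sex") for i in range(1, 10)]
        trait_defs += [("TRAIT_COLOR", "chr02", "berry_color")]
        trait_defs += [("TRAIT_SEED", "chr18", "seed_development")]
        trait_defs += [("TRAIT_MUSCAT", "chr05", "berry_taste")]
        trait_defs += [
            (f"TRAIT_MPZ_{i:02d}", "chr03", "methoxypyrazine") for i in range(1, 12)
        ]
    for k, (mid, chrom, ann) in enumerate(trait_defs):
        marker_rows.append(
            {
                "marker_id": mid,
                "chromosome": chrom,
                "position": 26_000_000 + k * 1_000,
                "source": "trait_candidate",
                "species_of_origin": "",
                "is_plastid": False,
                "trait_annotation": ann,
            }
        )
    n_auto = len(marker_rows)

    plastid_ids = [f"CP_{i:02d}" for i in range(1, cfg.n_plastid_markers + 1)]
    for i, mid in enumerate(plastid_ids):
        marker_rows.append(
            {
                "marker_id": mid,
                "chromosome": cfg.plastid_chromosome,
                "position": 1_000 * (i + 1),
                "source": "prior_chip",
                "species_of_origin": "",
                "is_plastid": True,
                "trait_annotation": "",
            }
        )
    markers = pd.DataFrame(marker_rows)
    marker_ids = list(markers["marker_id"])
    col_of = {m: j for j, m in enumerate(marker_ids)}

    if not 0 <= cfg.duplicate_discordance <= n_regular:
        raise ConfigError("duplicate_discordance exceeds the regular marker count")

    # ---- founders ----------------------------------------------------
    rng_f = rngs["founders"]
    lo, hi = cfg.ancestral_maf_range
    p_anc = rng_f.uniform(lo, hi, n_auto)

    founder_ids: list[str] = []
    founder_pop: dict[str, PopulationConfig] = {}
    founder_codes: list[np.ndarray] = []
    prefix_of = {}
    for pop in cfg.populations:
        prefix = pop.name[:3].upper()
        if prefix in prefix_of.values():
            prefix = pop.name[:4].upper()
        prefix_of[pop.name] = prefix
        F = pop.fst
        p_pop = rng_f.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
        p_pop = np.clip(p_pop, 1e-9, 1 - 1e-9)
        for i in range(pop.n_founders):
            sid = f"{prefix}_{i + 1:03d}"
            founder_ids.append(sid)
            founder_pop[sid] = pop
            founder_codes.append(
                rng_f.binomial(2, p_pop).astype(np.int8)
            )

    true_codes: dict[str, np.ndarray] = dict(zip(founder_ids, founder_codes))
    sample_order: list[str] = list(founder_ids)

    # ---- pedigree / transmission --------------------------------------
    rng_t = rngs["transmission"]
    parents: dict[str, tuple[str, str]] = {s: ("", "") for s in founder_ids}
    prefix_counter: dict[str, int] = {}
    offspring_ids: list[str] = []
    for cross in cfg.crosses:
        for parent in (cross.mother, cross.father):
            if parent not in true_codes:
                raise ConfigError(
                    f"cross references unknown parent {parent!r} "
                    f"(parents must be founders or earlier offspring)"
                )
        for _ in range(cross.n_offspring):
            k = prefix_counter.get(cross.offspring_prefix, 0) + 1
            prefix_counter[cross.offspring_prefix] = k
            oid = f"{cross.offspring_prefix}_{k:03d}"
            if oid in true_codes:
                raise ConfigError(f"offspring id collision: {oid!r}")
            g = _gamete(true_codes[cross.mother], rng_t) + _gamete(
                true_codes[cross.father], rng_t
            )
            true_codes[oid] = g.astype(np.int8)
            parents[oid] = (cross.mother, cross.father)
            offspring_ids.append(oid)
            sample_order.append(oid)

    # ---- trait loci ---------------------------------------------------
    rng_tr = rngs["traits"]
    phenotypes: dict[str, dict[str, object]] = {s: {} for s in sample_order}
    trait_truth = TraitTruth()
    if cfg.plant_traits:
        trait_truth, phenotypes = _plant_traits(
            cfg, rng_tr, sample_order, founder_ids, parents, true_codes, col_of
        )

    # ---- plastid haplotypes --------------------------------------------
    rng_p = rngs["plastid"]
    haplotypes = _chlorotype_patterns(cfg.n_plastid_markers, cfg.n_chlorotypes)
    freqs = np.asarray(cfg.chlorotype_freqs[: cfg.n_chlorotypes], dtype=float)
    freqs = freqs / freqs.sum()
    hap_index: dict[str, int] = {}
    for sid in sample_order:
        mother = parents[sid][0]
        if mother:
            hap_index[sid] = hap_index[mother]
        else:
            hap_index[sid] = int(rng_p.choice(cfg.n_chlorotypes, p=freqs))
    plastid_codes = {
        sid: np.array(
            [0 if ch == "A" else 2 for ch in haplotypes[hap_index[sid]]],
            dtype=np.int8,
        )
        for sid in sample_order
    }

    # ---- assemble the true matrix --------------------------------------
    n_markers_total = len(marker_ids)
    observed = np.empty((len(sample_order), n_markers_total), dtype=np.int8)
    for i, sid in enumerate(sample_order):
        observed[i, :n_auto] = true_codes[sid]
        observed[i, n_auto:] = plastid_codes[sid]

    # ---- failing ("noisy") markers --------------------------------------
    rng_n = rngs["noisy"]
    regular_idx = np.arange(n_regular)
    noisy_idx = np.sort(
        rng_n.choice(regular_idx, size=min(cfg.n_noisy_markers, n_regular), replace=False)
    )
    if cfg.noisy_replacement_rate > 0 and noisy_idx.size:
        # cluster-collapse miscalls: a corrupted call is always wrong and
        # always homozygous (hets fall into a hom cluster, homs into the
        # opposite one)
        block = observed[:, noisy_idx]
        hit = rng_n.random(block.shape) < cfg.noisy_replacement_rate
        rand_hom = rng_n.integers(0, 2, block.shape, dtype=np.int8) * 2
        wrong = np.where(block == 1, rand_hom, 2 - block).astype(np.int8)
        block[hit] = wrong[hit]
        observed[:, noisy_idx] = block

    # ---- panel-wide genotyping error (regular, non-failing markers) -----
    rng_e = rngs["error"]
    clean_idx = np.setdiff1d(regular_idx, noisy_idx)
    observed[:, clean_idx] = _single_step_error(
        observed[:, clean_idx], cfg.genotyping_error_rate, rng_e
    )

    # ---- duplicates ------------------------------------------------------
    rng_d = rngs["duplicates"]
    dup_pairs: list[tuple[str, str]] = []
    dup_rows: list[np.ndarray] = []
    dup_sources = [s for s in founder_ids if founder_pop[s].name == cfg.populations[0].name]
    if cfg.n_duplicate_pairs > len(dup_sources):
        raise ConfigError("not enough founders in the first population for duplicates")
    for src in dup_sources[: cfg.n_duplicate_pairs]:
        dup_id = f"{src}-DUP"
        row = observed[sample_order.index(src)].copy()
        flip_at = rng_d.choice(regular_idx, size=cfg.duplicate_discordance, replace=False)
        for j in flip_at:
            current = row[j]
            choices = [c for c in (0, 1, 2) if c != current]
            row[j] = choices[int(rng_d.integers(0, len(choices)))]
        dup_pairs.append((src, dup_id))
        dup_rows.append(row)
        parents[dup_id] = ("", "")
        hap_index[dup_id] = hap_index[src]
        phenotypes[dup_id] = dict(phenotypes[src])
    if dup_rows:
        observed = np.vstack([observed, np.array(dup_rows, dtype=np.int8)])
        sample_order = sample_order + [d for _, d in dup_pairs]

    # ---- missingness ------------------------------------------------------
    rng_miss = rngs["missingness"]
    crossed = {c.mother for c in cfg.crosses} | {c.father for c in cfg.crosses}
    wild_founders = [s for s in founder_ids if founder_pop[s].is_wild]
    # prefer wild founders outside the pedigree so the planted QC failure
    # does not also thin the evaluable duo/trio transmissions
    pool = [s for s in wild_founders if s not in crossed] + [
        s for s in wild_founders if s in crossed
    ]
    low_cr_samples = tuple(pool[: cfg.n_low_call_rate_samples])
    dup_of = {d: s for s, d in dup_pairs}
    for i, sid in enumerate(sample_order):
        base_sid = dup_of.get(sid, sid)
        pop = founder_pop.get(base_sid)
        rate = cfg.missing_rate_base
        if pop is not None and pop.is_wild:
            rate += cfg.missing_rate_wild_boost
        if sid in low_cr_samples:
            rate = 1.0 - cfg.low_call_rate_target
        if rate > 0:
            mask = rng_miss.random(n_regular) < rate
            row = observed[i, :n_regular]
            row[mask] = -1
            observed[i, :n_regular] = row

    gm = GenotypeMatrix(sample_order, marker_ids, observed)

    # ---- metadata ---------------------------------------------------------
    samples = _sample_metadata(
        cfg, sample_order, founder_pop, parents, dup_of, phenotypes
    )

    po_pairs = tuple(
        tuple(sorted((child, parent)))
        for child, (m, f) in parents.items()
        for parent in (m, f)
        if parent
    )
    trios = tuple(
        (child, m, f) for child, (m, f) in parents.items() if m and f
    )
    truth = PanelTruth(
        po_pairs=po_pairs,
        trios=trios,
        duplicate_pairs=tuple(dup_pairs),
        chlorotypes={s: haplotypes[hap_index[s]] for s in sample_order},
        plastid_marker_ids=tuple(plastid_ids),
        noisy_markers=tuple(marker_ids[j] for j in noisy_idx),
        clean_markers=tuple(marker_ids[j] for j in clean_idx),
        low_call_rate_samples=low_cr_samples,
        traits=trait_truth,
    )
    return PanelSimulation(gm=gm, samples=samples, markers=markers, truth=truth)


def _chlorotype_patterns(n_markers: int, k: int) -> list[str]:
    """K distinct haplotype strings; the first marker is kept monomorphic."""
    if n_markers < 2:
        raise ConfigError("need at least 2 plastid markers")
    base = ["A" * (n_markers - 1), "B" * (n_markers - 1)]
    i = 0
    while len(base) < k:
        # alternate patterns of increasing period, all distinct
        pat = "".join(
            "AB"[(j // (i + 1)) % 2] for j in range(n_markers - 1)
        )
        if pat not in base:
            base.append(pat)
        i += 1
        if i > 4 * k:
            raise ConfigError(f"cannot build {k} distinct plastid haplotypes")
    return ["A" + b for b in base[:k]]


def _plant_traits(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_order: list[str],
    founder_ids: list[str],
    parents: dict[str, tuple[str, str]],
    true_codes: dict[str, np.ndarray],
    col_of: dict[str, int],
) -> tuple[TraitTruth, dict[str, dict[str, object]]]:
    """Overwrite trait-locus genotypes and derive deterministic phenotypes."""
    trait_truth_phenotypes: dict[str, dict[str, object]] = {
        s: {} for s in sample_order
    }

    crossed_mothers = {c.mother for c in cfg.crosses}
    crossed_fathers = {c.father for c in cfg.crosses}

    # -- flower sex: one locus, allele M (female-sterile -> male plants),
    #    allele F (male-sterile -> female plants), H (hermaphrodite).
    diplotype: dict[str, tuple[str, str]] = {}
    for sid in founder_ids:
        if sid in crossed_mothers:
            diplotype[sid] = ("H", "H")  # seed parents must bear fruit
        elif sid in crossed_fathers:
            diplotype[sid] = ("H", "M") if rng.random() < 0.4 else ("H", "H")
        else:
            u = rng.random()
            if u < 0.45:
                diplotype[sid] = ("H", "H")
            elif u < 0.65:
                diplotype[sid] = ("H", "M")
            elif u < 0.75:
                diplotype[sid] = ("M", "M")
            else:
                diplotype[sid] = ("F", "F")
    for sid in sample_order:
        m, f = parents[sid]
        if not m:
            continue
        ma = diplotype[m][int(rng.integers(0, 2))]
        fa = diplotype[f][int(rng.integers(0, 2))]
        if sid in crossed_mothers:
            # a future seed parent must be hermaphrodite: take the H copy
            ma = "H" if "H" in diplotype[m] else ma
            fa = "H" if "H" in diplotype[f] else fa
        diplotype[sid] = (ma, fa)

    def sex_of(d: tuple[str, str]) -> str:
        if "M" in d:
            return "male"
        if "F" in d:
            return "female"
        return "hermaphrodite"

    sex_ids = [f"TRAIT_SEX_{i:02d}" for i in range(1, 10)]
    fs_ids, ms_ids = sex_ids[:4], sex_ids[4:]
    for sid in sample_order:
        d = diplotype[sid]
        n_m = d.count("M")
        n_f = d.count("F")
        g = true_codes[sid]
        for mid in fs_ids:
            g[col_of[mid]] = n_m
        for mid in ms_ids:
            g[col_of[mid]] = n_f
        trait_truth_phenotypes[sid]["flower_sex"] = sex_of(d)

    # planted recombination: entries alternate fs/ms faulty markers
    recombinant: list[tuple[str, int]] = []
    used: set[str] = set()
    for k, n_cases in enumerate(cfg.sex_recombination):
        if k % 2 == 0:
            mid = fs_ids[k // 2]
            eligible = [
                s
                for s in sample_order
                if trait_truth_phenotypes[s]["flower_sex"] != "male" and s not in used
            ]
            chosen = list(rng.choice(eligible, size=n_cases, replace=False))
            for s in chosen:
                true_codes[s][col_of[mid]] = 1  # spurious B: predicts male
        else:
            mid = ms_ids[k // 2]
            eligible = [
                s
                for s in sample_order
                if trait_truth_phenotypes[s]["flower_sex"] != "female" and s not in used
            ]
            chosen = list(rng.choice(eligible, size=n_cases, replace=False))
            for s in chosen:
                true_codes[s][col_of[mid]] = 2  # spurious BB: predicts female
        used.update(chosen)
        recombinant.append((mid, n_cases))

    female_rules = tuple(
        TraitRule(
            rule_id=f"sex_{mid}",
            trait="flower_sex",
            marker_ids=(mid,),
            predicate="allele_present",
            predicted_class="male",
        )
        for mid in fs_ids
    )
    male_rules = tuple(
        TraitRule(
            rule_id=f"sex_{mid}",
            trait="flower_sex",
            marker_ids=(mid,),
            predicate="homozygous_B",
            predicted_class="female",
        )
        for mid in ms_ids
    )

    # -- berry colour (dominant B), seed development (dominant B ->
    #    seedless), muscat (dominant B). Males bear no fruit: berry
    #    phenotypes are undefined for them.
    jc = col_of["TRAIT_COLOR"]
    js = col_of["TRAIT_SEED"]
    jm = col_of["TRAIT_MUSCAT"]

    # -- methoxypyrazine haplotypes over 11 markers -------------------------
    mpz_ids = [f"TRAIT_MPZ_{i:02d}" for i in range(1, 12)]
    mpz_cols = [col_of[m] for m in mpz_ids]
    vin_prefix = cfg.populations[0].name[:3].upper()
    syl_prefix = cfg.populations[1].name[:3].upper()
    uncrossed_vin = [
        s
        for s in founder_ids
        if s.startswith(vin_prefix) and s not in crossed_mothers | crossed_fathers
    ]
    syl = [s for s in founder_ids if s.startswith(syl_prefix)]
    group1 = uncrossed_vin[:3] + syl[:3]
    group2 = uncrossed_vin[3:4] + syl[3:7]
    v1_codes = [2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1]
    v2_codes = [1] * 11
    for sid in sample_order:
        g = true_codes[sid]
        if sid in group1:
            g[mpz_cols] = v1_codes
        elif sid in group2:
            g[mpz_cols] = v2_codes
        else:
            g[mpz_cols] = 0
    hap1 = TraitRule(
        rule_id="mpz_hap1",
        trait="berry_taste",
        marker_ids=tuple(mpz_ids),
        predicate="haplotype_match",
        predicted_class="herbaceous",
        expected_vector=("BB",) * 5 + ("AB",) * 5 + ("any",),
    )
    hap2 = TraitRule(
        rule_id="mpz_hap2",
        trait="berry_taste",
        marker_ids=tuple(mpz_ids),
        predicate="haplotype_match",
        predicted_class="herbaceous",
        expected_vector=("AB",) * 11,
    )

    mpz_carriers = set(group1) | set(group2)
    for sid in sample_order:
        sex = trait_truth_phenotypes[sid]["flower_sex"]
        g = true_codes[sid]
        if sex == "male":
            trait_truth_phenotypes[sid]["berry_color_oiv"] = None
            trait_truth_phenotypes[sid]["seed_development"] = None
            trait_truth_phenotypes[sid]["berry_taste"] = None
            continue
        colored = g[jc] >= 1
        trait_truth_phenotypes[sid]["berry_color_oiv"] = int(
            (6 if rng.random() < 0.6 else 5) if colored else (1 if rng.random() < 0.6 else 2)
        )
        trait_truth_phenotypes[sid]["seed_development"] = (
            "none" if g[js] >= 1 else "complete"
        )
        if g[jm] >= 1:
            taste = "muscat"
        elif sid in mpz_carriers:
            taste = "herbaceous"
        else:
            u = rng.random()
            taste = (
                "none" if u < 0.7 else "foxy" if u < 0.85 else "muscat-like aromatic"
            )
        trait_truth_phenotypes[sid]["berry_taste"] = taste

    color_collapse = {1: "non-colored", 2: "non-colored", 5: "colored", 6: "colored"}
    truth = TraitTruth(
        color_rule=TraitRule(
            rule_id="berry_color_dominant_B",
            trait="berry_color_oiv",
            marker_ids=("TRAIT_COLOR",),
            predicate="allele_present",
            predicted_class="colored",
        ),
        seed_rule=TraitRule(
            rule_id="seedless_dominant_B",
            trait="seed_development",
            marker_ids=("TRAIT_SEED",),
            predicate="allele_present",
            predicted_class="none",
        ),
        muscat_rule=TraitRule(
            rule_id="muscat_dominant_B",
            trait="berry_taste",
            marker_ids=("TRAIT_MUSCAT",),
            predicate="allele_present",
            predicted_class="muscat",
        ),
        female_sterility_rules=female_rules,
        male_sterility_rules=male_rules,
        haplotype_rules=(hap1, hap2),
        color_collapse=color_collapse,
        haplotype_groups={"mpz_hap1": sorted(group1), "mpz_hap2": sorted(group2)},
        recombinant_sex_markers=tuple(recombinant),
    )
    return truth, trait_truth_phenotypes


def _sample_metadata(
    cfg: SimulationConfig,
    sample_order: list[str],
    founder_pop: dict[str, PopulationConfig],
    parents: dict[str, tuple[str, str]],
    dup_of: dict[str, str],
    phenotypes: dict[str, dict[str, object]],
) -> pd.DataFrame:
    def classify(sid: str) -> tuple[str, str, str]:
        """-> (population, species, taxon_class)"""
        base = dup_of.get(sid, sid)
        pop = founder_pop.get(base)
        if pop is not None:
            if pop.name == cfg.populations[0].name:
                cls = "V. vinifera ssp. sativa"
            elif not pop.is_wild:
                cls = "V. vinifera ssp. sylvestris"
            else:
                cls = "non-vinifera"
            return pop.name, pop.species or pop.name, cls
        # offspring: hybrid iff any ancestor is wild
        def has_wild(s: str) -> bool:
            p = founder_pop.get(s)
            if p is not None:
                return p.is_wild
            m, f = parents[s]
            return bool(m and has_wild(m)) or bool(f and has_wild(f))

        if has_wild(sid):
            return "cross", "Vitis hybrid", "Vitis hybrid"
        return "cross", "V. vinifera", "V. vinifera ssp. sativa"

    rows = []
    for sid in sample_order:
        popname, species, cls = classify(sid)
        ph = phenotypes.get(sid, {})
        m, f = parents.get(sid, ("", ""))
        rows.append(
            {
                "sample_id": sid,
                "population": popname,
                "species": species,
                "taxon_class": cls,
                "mother_id": m,
                "father_id": f,
                "duplicate_of": dup_of.get(sid, ""),
                "flower_sex": ph.get("flower_sex"),
                "seed_development": ph.get("seed_development"),
                "berry_color_oiv": ph.get("berry_color_oiv"),
                "berry_taste": ph.get("berry_taste"),
            }
        )
    df = pd.DataFrame(rows)
    df["berry_color_oiv"] = df["berry_color_oiv"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# Candidate-variant VCF simulation
# ---------------------------------------------------------------------------

_SAFE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))
_AMBI_PAIRS = (("A", "T"), ("C", "G"))


def simulate_candidate_vcf(
    cfg: SimulationConfig, out_path: str | Path
) -> dict[str, list[str]]:
    """Write a synthetic candidate VCF; return the planted filter truth.

    For each (species, chromosome) cell the file plants clean biallelic
    SNVs plus controlled numbers of records failing exactly one filter
    (QUAL below threshold, indel, multiallelic, one low-DP called sample,
    >20% missing genotypes, A/T or C/G polymorphism) and pairs of
    otherwise-clean variants 20 nt apart (proximity-flag targets). The
    returned mapping gives, per record ID, the list of filter flags the
    record should receive — empty for clean records.

    Variants sit on a 1 kb grid so that nothing is accidentally proximal.
    """
    v = cfg.candidate_vcf
    rng = _rngs(cfg.seed)["vcf"]
    species = [p.name for p in cfg.populations]
    samples = [f"S{i + 1:02d}" for i in range(v.n_samples)]
    truth: dict[str, list[str]] = {}

    lines: list[str] = ["##fileformat=VCFv4.2"]
    for chrom in cfg.chromosomes:
        lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##INFO=<ID=SPECIES,Number=1,Type=String,Description="Species of origin">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]

    def genotype_fields(
        n_missing: int = 0, low_dp_sample: int | None = None
    ) -> list[str]:
        p = rng.uniform(0.1, 0.9)
        g = rng.binomial(2, p, v.n_samples)
        gt = np.array(["0/0", "0/1", "1/1"])[g]
        fields = []
        missing_at = set(
            rng.choice(v.n_samples, size=n_missing, replace=False).tolist()
            if n_missing
            else []
        )
        for i in range(v.n_samples):
            if i in missing_at:
                fields.append("./.:.")
            elif i == low_dp_sample:
                fields.append(f"0/1:{v.low_depth}")
            else:
                fields.append(f"{gt[i]}:{v.depth}")
        return fields

    n_missing_for_fail = int(np.ceil(v.n_samples * 0.25)) + 1  # comfortably > 20%

    for chrom in cfg.chromosomes:
        records: list[tuple[int, str]] = []
        slot = 0

        def next_pos() -> int:
            nonlocal slot
            pos = 100_000 + slot * 1_000
            slot += 1
            return pos

        for sp in species:
            cell_plan: list[tuple[str, int]] = [
                ("clean", v.n_clean_per_cell),
                ("low_qual", v.n_low_qual),
                ("indel", v.n_indel),
                ("multiallelic", v.n_multiallelic),
                ("low_depth", v.n_low_depth),
                ("high_missing", v.n_high_missing),
                ("at_cg", v.n_at_cg),
            ]
            for kind, count in cell_plan:
                for k in range(count):
                    pos = next_pos()
                    rid = f"CAND_{chrom}_{pos:09d}"
                    ref, alt = _SAFE_PAIRS[k % len(_SAFE_PAIRS)]
                    qual = v.clean_qual
                    fmt = None
                    flags: list[str] = []
                    if kind == "low_qual":
                        qual = v.low_qual
                        flags = ["low_qual"]
                    elif kind == "indel":
                        ref, alt = ref + alt, ref
                        flags = ["indel"]
                    elif kind == "multiallelic":
                        others = [b for b in "ACGT" if b not in (ref, alt)]
                        # avoid ambiguous sub-pairs so only one flag applies
                        alt = f"{alt},{others[0]}"
                        flags = ["multiallelic"]
                    elif kind == "low_depth":
                        fmt = genotype_fields(low_dp_sample=0)
                        flags = ["low_depth"]
                    elif kind == "high_missing":
                        fmt = genotype_fields(n_missing=n_missing_for_fail)
                        flags = ["high_missing"]
                    elif kind == "at_cg":
                        ref, alt = _AMBI_PAIRS[k % 2]
                        flags = ["at_cg"]
                    if fmt is None:
                        fmt = genotype_fields()
                    truth[rid] = flags
                    records.append(
                        (
                            pos,
                            f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t{qual:g}\t.\t"
                            f"SPECIES={sp}\tGT:DP\t" + "\t".join(fmt),
                        )
                    )
            for _ in range(v.n_proximal_pairs):
                base = next_pos()
                for off in (0, 20):
                    pos = base + off
                    rid = f"CAND_{chrom}_{pos:09d}"
                    ref, alt = _SAFE_PAIRS[off % len(_SAFE_PAIRS)]
                    fmt = genotype_fields()
                    truth[rid] = ["proximity"]
                    records.append(
                        (
                            pos,
                            f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t{v.clean_qual:g}\t.\t"
                            f"SPECIES={sp}\tGT:DP\t" + "\t".join(fmt),
                        )
                    )
        records.sort(key=lambda r: r[0])
        lines.extend(line for _, line in records)

    out_path = Path(out_path)
    out_path.write_text("\n".join(lines) + "\n")
    return truth


# ---------------------------------------------------------------------------
# YAML round-trip for the CLI
# ---------------------------------------------------------------------------


def config_from_yaml(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from YAML; omitted keys keep their defaults."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "populations" in data:
        data["populations"] = tuple(
            PopulationConfig(**p) for p in data["populations"]
        )
    if "crosses" in data:
        data["crosses"] = tuple(CrossConfig(**c) for c in data["crosses"])
    if "candidate_vcf" in data:
        data["candidate_vcf"] = CandidateVcfConfig(**data["candidate_vcf"])
    for key in ("chromosomes", "chlorotype_freqs", "sex_recombination"):
        if key in data:
            data[key] = tuple(data[key])
    if "ancestral_maf_range" in data:
        data["ancestral_maf_range"] = tuple(data["ancestral_maf_range"])
    if "crosses" not in data:
        data["crosses"] = default_crosses()
    return SimulationConfig(**data)
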