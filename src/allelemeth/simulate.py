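"""Synthetic cohorts and CCS-like bisulfite amplicon reads with ground truth.

The generator emulates the statistical structure the analysis assumes: a
1.4 kb amplicon carrying three haplotype-marker SNPs (catalogue TGT / GAG /
TGG, TGT the risk haplotype) in complete linkage with a C>T CpG-SNP
(TGT carries C, the others T), a biallelic VNTR (V2/V3) in strong LD with
the risk haplotype, coupled early-environment exposures (SOB / OC / ACE)
that feed a polyenviromic risk score, per-site methylation models
(stochastic, additive haplotype+PERS, allele-specific, CpG-SNP structural),
phenotypes generated along a genotype -> DNAm -> cognition mediation path,
and full-length reads with bisulfite conversion efficiency, inappropriate
conversion, and substitution sequencing error.

Everything is driven by one integer seed; the same seed yields
byte-identical FASTQ files and truth tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .align import FastqRead, write_fastq
from .reference import AmpliconReference, build_reference
from .scores import PersWeights, compute_pers

__all__ = [
    "ConfigError",
    "SiteModel",
    "ExposureModel",
    "PhenotypeModel",
    "ReadModel",
    "SimulationConfig",
    "SubjectRecord",
    "synthetic_study_reference",
    "simulate_cohort",
    "simulate_methylation",
    "simulate_phenotypes",
    "simulate_reads",
    "simulate_dataset",
    "SimulatedDataset",
]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# the synthetic study amplicon
# ---------------------------------------------------------------------------

STUDY_CHROM = "chr10"
STUDY_START = 104_594_471
STUDY_END = 104_595_888
MARKER_COORDS = (104_594_906, 104_595_248, 104_595_420)
CPG_SNP_COORD = 104_595_719
VMS_COORDS = (104_595_032, 104_595_063, 104_595_714)


def synthetic_study_reference(seed: int = 20221020) -> AmpliconReference:
    """A synthetic stand-in for the study amplicon (the real hg19 sequence is
    not bundled): a random 1418-mer pinned to the locus coordinate frame with
    the three marker SNPs, the CpG-SNP, and CpG dinucleotides at the four
    variably-methylated-site coordinates the analysis names.
    """
    rng = np.random.default_rng(seed)
    n = STUDY_END - STUDY_START + 1
    seq = rng.choice(list("ACGT"), size=n, p=[0.3, 0.2, 0.2, 0.3]).tolist()

    def put(coord, bases):
        off = coord - STUDY_START
        seq[off:off + len(bases)] = list(bases)

    # marker SNPs: reference carries the risk haplotype TGT
    for coord, base in zip(MARKER_COORDS, "TGT"):
        put(coord, base)
        # avoid accidental C immediately before a marker (keeps calls clean)
        off = coord - STUDY_START
        if off > 0 and seq[off - 1] == "C":
            seq[off - 1] = "A"
    # the four VMS: CpG dinucleotides; CpG-SNP reference base is C
    for coord in (*VMS_COORDS, CPG_SNP_COORD):
        put(coord, "CG")

    annotation = {
        "name": "synthetic_amplicon",
        "chrom": STUDY_CHROM,
        "start": STUDY_START,
        "end": STUDY_END,
        "snps": [
            {"id": "rs743575", "coord": MARKER_COORDS[0], "alleles": ["T", "G"]},
            {"id": "rs4919687", "coord": MARKER_COORDS[1], "alleles": ["G", "A"]},
            {"id": "rs3781287", "coord": MARKER_COORDS[2], "alleles": ["T", "G"]},
            {"id": "rs3781286", "coord": CPG_SNP_COORD, "alleles": ["C", "T"],
             "role": "cpg_snp"},
        ],
        "haplotypes": [
            {"label": "TGT", "is_risk": True, "cpg_snp_allele": "C"},
            {"label": "GAG", "cpg_snp_allele": "T"},
            {"label": "TGG", "cpg_snp_allele": "T"},
        ],
    }
    return build_reference("".join(seq), annotation)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SiteModel:
    """Methylation model for one named site.

    kind: "stochastic" (Beta noise around a baseline), "additive"
    (logit-linear in haplotype offset and PERS), "allele_specific"
    (haplotype-determined mean) or "cpg_snp" (defined only on C-carrying
    alleles).  Offsets and slope act on the logit scale, which keeps means
    inside (0, 1).
    """

    site: str
    kind: str = "stochastic"
    baseline: float = 0.5
    hap_offsets: dict = field(default_factory=dict)  # label -> logit offset
    pers_slope: float = 0.0
    dispersion: float = 80.0  # Beta concentration; larger = less noise


def default_site_models() -> list[SiteModel]:
    """The four variably methylated sites with the effect structure the
    analysis targets: one stochastic, one additive (haplotype + PERS), one
    allele-specific, one CpG-SNP (structurally allele-specific)."""
    return [
        SiteModel("CpG_5032", "stochastic", baseline=0.28),
        SiteModel("CpG_5063", "additive", baseline=0.60,
                  hap_offsets={"TGT": 0.0, "GAG": 0.4, "TGG": 1.0},
                  pers_slope=0.45),
        SiteModel("CpG_5714", "allele_specific", baseline=0.85,
                  hap_offsets={"TGT": 0.6, "GAG": -1.6, "TGG": -0.4}),
        SiteModel("CpG-SNP_5719", "cpg_snp", baseline=0.90),
    ]


@dataclass
class ExposureModel:
    """Coupled exposure sampling via a sequential logistic factorisation:
    education | sex -> ACE | education -> SOB -> OC | SOB, sex.

    Marginal prevalences are calibrated exactly (intercepts solved against
    the realised covariates), so couplings change dependence, not margins.
    Default prevalences follow the patient sample (SOB 0.23, OC 0.36,
    ACE 0.55; tertiary education 0.71).
    """

    p_sob: float = 0.23
    p_oc: float = 0.36
    p_ace: float = 0.55
    p_tertiary: float = 0.71
    lor_edu_female: float = 0.9   # higher education in women
    lor_ace_lowedu: float = 0.9   # more ACE with non-tertiary education
    lor_oc_sob: float = 0.9       # more OC in winter birth
    lor_oc_male: float = 0.8      # more OC in men


@dataclass
class PhenotypeModel:
    """Linear phenotype models with a genotype -> DNAm -> phenotype path.

    ``b`` is the coefficient on subject-level averaged DNAm at the mediator
    site, ``c_prime`` the direct effect of the risk-allele count; scales are
    arbitrary score units (roughly T-score sized by default).
    """

    mediator_site: str = "CpG-SNP_5719"
    intercept: float = 40.0
    b: dict = field(default_factory=lambda: {"verbal_fluency": 7.7})
    c_prime: dict = field(default_factory=dict)  # phenotype -> direct effect
    sex_effect: float = 1.0
    age_effect: float = -0.15
    education_effect: float = 3.0
    noise_sd: float = 9.0
    sib_intercept: float = -1.3  # logistic; ~22% prevalence
    sib_slope_dnam: float = 0.0
    p_depression: float = 0.045  # P(PANSS G6 >= 4)

    PHENOTYPES = ("verbal_fluency", "episodic_verbal_memory",
                  "cognitive_flexibility", "cognitive_inhibition",
                  "working_memory")


@dataclass
class ReadModel:
    """CCS-like read generation: per-allele Poisson depth, substitution
    error, conversion efficiency P(unmethylated C read as T) and
    inappropriate conversion P(methylated C read as T)."""

    depth_mean: float = 30.0
    error_rate: float = 0.005
    conversion_efficiency: float = 0.99
    inappropriate_conversion: float = 0.01
    base_quality: int = 40
    lowq_fraction: float = 0.0  # fraction of reads emitted at lowq_quality
    lowq_quality: int = 20

    def __post_init__(self):
        if self.depth_mean < 1:
            raise ConfigError("depth mean must be >= 1")
        for p in (self.error_rate, self.conversion_efficiency,
                  self.inappropriate_conversion, self.lowq_fraction):
            if not 0 <= p <= 1:
                raise ConfigError("rates must lie in [0, 1]")


@dataclass
class SimulationConfig:
    n_patients: int = 66
    n_controls: int = 63
    haplotype_freqs: dict = field(
        default_factory=lambda: {"TGT": 0.45, "GAG": 0.40, "TGG": 0.15}
    )
    vntr_v3_freq: float = 0.59  # V2 minor-allele frequency 0.41
    vntr_ld_r: float = 0.7      # correlation of risk-haplotype and V3 alleles
    exposure_model: ExposureModel = field(default_factory=ExposureModel)
    site_models: list = field(default_factory=default_site_models)
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    read_model: ReadModel = field(default_factory=ReadModel)
    pers_weights: PersWeights = field(default_factory=PersWeights)
    default_cpg_meth: float = 0.90  # non-VMS CpG baseline (gene body)
    cph_meth: float = 0.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"haplotype frequencies sum to {total}, not 1")
        if not all(0 <= p <= 1 for p in self.haplotype_freqs.values()):
            raise ConfigError("haplotype frequencies must lie in [0, 1]")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    id: str
    group: str  # "patient" | "control"
    sex: str    # "F" | "M"
    age: float
    education: str  # "tertiary" | "non-tertiary"
    smoking: bool
    diplotype: tuple
    cpg_snp_genotype: str
    vntr: str  # "V2V2" | "V2V3" | "V3V3"
    SOB: bool
    OC: bool
    ACE: bool
    pers: float
    truth_meth: np.ndarray | None = None  # (2 alleles, n_sites), NaN = absent
    phenotypes: dict = field(default_factory=dict)

    @property
    def risk_allele_count(self) -> int:
        return sum(h == "TGT" for h in self.diplotype)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrated_bernoulli(rng, target_p, lin_pred):
    """Bernoulli draws whose marginal hits ``target_p`` exactly in
    expectation: the intercept is solved against the realised linear
    predictor (couplings shift dependence, not the margin)."""
    from scipy.optimize import brentq

    lin = np.asarray(lin_pred, dtype=float)
    if np.ptp(lin) == 0:
        return rng.random(len(lin)) < target_p
    f = lambda b0: _expit(b0 + lin).mean() - target_p
    b0 = brentq(f, -30, 30)
    return rng.random(len(lin)) < _expit(b0 + lin)


def _vntr_allele_probs(p_risk, q_v3, r):
    """P(V3 | risk allele) and P(V3 | other), targeting correlation r between
    the risk-haplotype and V3 indicators at the allele level."""
    s = np.sqrt(q_v3 * (1 - q_v3))
    p1 = q_v3 + r * s * np.sqrt((1 - p_risk) / p_risk)
    p0 = q_v3 - r * s * np.sqrt(p_risk / (1 - p_risk))
    return p1, p0


def max_attainable_vntr_r(p_risk, q_v3) -> float:
    """Largest |r| for which both conditional V3 probabilities stay in [0,1]."""
    s = np.sqrt(q_v3 * (1 - q_v3))
    bounds = [
        (1 - q_v3) / (s * np.sqrt((1 - p_risk) / p_risk)),
        q_v3 / (s * np.sqrt(p_risk / (1 - p_risk))),
    ]
    return float(min(bounds))


def simulate_cohort(config: SimulationConfig,
                    reference: AmpliconReference,
                    rng: np.random.Generator | None = None) -> list[SubjectRecord]:
    """Sample a cohort: coupled exposures, Hardy-Weinberg diplotypes, a VNTR
    in LD with the risk haplotype, and PERS."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_patients + config.n_controls
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    em = config.exposure_model

    p_risk = config.haplotype_freqs.get("TGT", 0.0)
    if not 0 < p_risk < 1 or not 0 < config.vntr_v3_freq < 1:
        if abs(config.vntr_ld_r) > 0:
            raise ConfigError("LD target requires both loci polymorphic")
    r_max = max_attainable_vntr_r(p_risk, config.vntr_v3_freq)
    if abs(config.vntr_ld_r) > r_max + 1e-12:
        raise ConfigError(
            f"vntr_ld_r={config.vntr_ld_r} infeasible for these frequencies; "
            f"attainable bound is {r_max:.3f}"
        )
    p_v3_risk, p_v3_other = _vntr_allele_probs(
        p_risk, config.vntr_v3_freq, config.vntr_ld_r
    )

    sex = np.where(rng.random(n) < 0.5, "F", "M")
    female = (sex == "F").astype(float)
    age = np.clip(rng.normal(27.5, 6.8, n), 18, 45)
    tertiary = _calibrated_bernoulli(rng, em.p_tertiary, em.lor_edu_female * female)
    ace = _calibrated_bernoulli(rng, em.p_ace, em.lor_ace_lowedu * (~tertiary))
    sob = rng.random(n) < em.p_sob
    oc = _calibrated_bernoulli(
        rng, em.p_oc, em.lor_oc_sob * sob + em.lor_oc_male * (1 - female)
    )
    smoking = rng.random(n) < 0.35

    labels = list(config.haplotype_freqs)
    freqs = np.array([config.haplotype_freqs[l] for l in labels])
    hap_idx = rng.choice(len(labels), size=(n, 2), p=freqs)
    linked = {h.label: h.linked_cpg_snp_allele or "?" for h in reference.haplotypes}

    subjects = []
    for i in range(n):
        diplotype = tuple(labels[j] for j in hap_idx[i])
        vntr_alleles = []
        for h in diplotype:
            p_v3 = p_v3_risk if h == "TGT" else p_v3_other
            vntr_alleles.append("V3" if rng.random() < p_v3 else "V2")
        exposures = {"SOB": bool(sob[i]), "OC": bool(oc[i]), "ACE": bool(ace[i])}
        subjects.append(
            SubjectRecord(
                id=f"S{i:04d}",
                group=groups[i],
                sex=str(sex[i]),
                age=float(age[i]),
                education="tertiary" if tertiary[i] else "non-tertiary",
                smoking=bool(smoking[i]),
                diplotype=diplotype,
                cpg_snp_genotype="".join(sorted(linked[h] for h in diplotype)),
                vntr="".join(sorted(vntr_alleles)),
                **exposures,
                pers=compute_pers(exposures, config.pers_weights),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# methylation truth
# ---------------------------------------------------------------------------

def _site_mean(model: SiteModel, hap: str, pers: float) -> float:
    from scipy.special import logit

    base = logit(model.baseline)
    if model.kind == "stochastic":
        return _expit(base)
    if model.kind == "additive":
        return _expit(base + model.hap_offsets.get(hap, 0.0)
                      + model.pers_slope * pers)
    if model.kind == "allele_specific":
        return _expit(base + model.hap_offsets.get(hap, 0.0))
    if model.kind == "cpg_snp":
        return _expit(base + model.hap_offsets.get(hap, 0.0))
    raise ConfigError(f"unknown site model kind {model.kind!r}")


def simulate_methylation(subject: SubjectRecord,
                         site_models: list[SiteModel],
                         reference: AmpliconReference,
                         rng: np.random.Generator,
                         default_cpg_meth: float = 0.90,
                         cph_meth: float = 0.0) -> np.ndarray:
    """Per-allele, per-site methylation probabilities (2, n_sites).

    Modelled sites follow their SiteModel with Beta noise at the configured
    dispersion; unmodelled CpGs sit at the hypermethylated gene-body default
    and CpH sites at ``cph_meth``.  A CpG-SNP site on a T-carrying allele is
    structurally absent (NaN).
    """
    models = {m.site: m for m in site_models}
    n_sites = len(reference.sites)
    truth = np.empty((2, n_sites))
    for a, hap in enumerate(subject.diplotype):
        hap_def = reference.haplotype(hap)
        for j, site in enumerate(reference.sites):
            model = models.get(site.short_name)
            if site.is_cpg_snp:
                if hap_def.linked_cpg_snp_allele != "C":
                    truth[a, j] = np.nan
                    continue
                mean = _site_mean(model, hap, subject.pers) if model else default_cpg_meth
            elif model is not None:
                mean = _site_mean(model, hap, subject.pers)
            else:
                mean = default_cpg_meth if site.context == "CpG" else cph_meth
            if model is not None and model.dispersion > 0 and 0 < mean < 1:
                k = model.dispersion
                truth[a, j] = rng.beta(mean * k, (1 - mean) * k)
            else:
                truth[a, j] = mean
    return truth


def subject_truth_dnam(subject: SubjectRecord, reference: AmpliconReference,
                       site: str) -> float:
    """Ground-truth subject-level DNAm at a site: allele average with the
    structural-zero rule for T alleles at a CpG-SNP."""
    j = [s.short_name for s in reference.sites].index(site)
    vals = subject.truth_meth[:, j]
    return float(np.where(np.isnan(vals), 0.0, vals).mean())


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(subject: SubjectRecord, model: PhenotypeModel,
                        reference: AmpliconReference,
                        rng: np.random.Generator) -> dict:
    """Phenotypes from covariates, mediator DNAm and the direct genotype
    path; SIB from a logistic model; PANSS totals as plain integers."""
    dnam = subject_truth_dnam(subject, reference, model.mediator_site)
    risk = subject.risk_allele_count
    covar = (
        model.intercept
        + model.sex_effect * (subject.sex == "F")
        + model.age_effect * (subject.age - 28.0)
        + model.education_effect * (subject.education == "tertiary")
    )
    phen = {}
    for name in PhenotypeModel.PHENOTYPES:
        phen[name] = float(
            covar
            + model.b.get(name, 0.0) * dnam
            + model.c_prime.get(name, 0.0) * risk
            + rng.normal(0.0, model.noise_sd)
        )
    p_sib = _expit(model.sib_intercept + model.sib_slope_dnam * dnam)
    phen["SIB"] = bool(rng.random() < p_sib)
    phen["PANSS_P"] = int(np.clip(rng.normal(27, 8.7), 7, 49))
    phen["PANSS_N"] = int(np.clip(rng.normal(20, 5.9), 7, 49))
    phen["PANSS_G"] = int(np.clip(rng.normal(31, 12), 16, 112))
    phen["PANSS_G6"] = int(4 + rng.integers(0, 3)) if rng.random() < model.p_depression \
        else int(1 + rng.integers(0, 3))
    return phen


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(subject: SubjectRecord, reference: AmpliconReference,
                   read_model: ReadModel, rng: np.random.Generator):
    """Full-length CCS-like reads for one subject.

    Per allele: Poisson depth (floored at 1); each read realises latent
    methylation states ~ Bernoulli(truth), picks a strand space (OT/OB with
    probability 1/2), applies conversion in that space, then substitution
    errors, and is emitted with constant base qualities plus a truth sidecar
    (allele, strand space, latent states per site).
    """
    rm = read_model
    site_offsets = np.array([s.coord - reference.start for s in reference.sites])
    n_sites = len(site_offsets)
    length = reference.length
    base_index = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        base_index[b] = i
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)

    reads, truth_rows = [], []
    for a, hap in enumerate(dict.fromkeys(subject.diplotype)):
        # homozygotes: one allele class carries the full depth of both copies
        copies = subject.diplotype.count(hap)
        allele_seq = np.frombuffer(reference.allele_seq(hap).encode(), dtype=np.uint8)
        c_pos = np.nonzero(allele_seq == ord("C"))[0]
        g_pos = np.nonzero(allele_seq == ord("G"))[0]
        # every C in an allele sits at a reference cytosine site
        c_site = np.searchsorted(site_offsets, c_pos)
        # CpG partner Gs mirror the plus-strand site's state in OB space
        partner_of = np.full(length, -1, dtype=np.int64)
        cpg = (site_offsets + 1 < length) \
            & (allele_seq[site_offsets] == ord("C")) \
            & (allele_seq[np.minimum(site_offsets + 1, length - 1)] == ord("G"))
        partner_of[site_offsets[cpg] + 1] = np.nonzero(cpg)[0]
        g_partner = partner_of[g_pos]
        truth = subject.truth_meth[subject.diplotype.index(hap)]
        depth = max(1, int(rng.poisson(rm.depth_mean * copies)))
        for k in range(depth):
            states = np.where(
                np.isnan(truth), -1, (rng.random(n_sites) < truth).astype(np.int8)
            )
            space = "OT" if rng.random() < 0.5 else "OB"
            seq = allele_seq.copy()
            if space == "OT":
                meth = states[c_site] == 1
                p_convert = np.where(meth, rm.inappropriate_conversion,
                                     rm.conversion_efficiency)
                conv = rng.random(len(c_pos)) < p_convert
                seq[c_pos[conv]] = ord("T")
            else:
                meth = np.where(g_partner >= 0, states[np.maximum(g_partner, 0)], 0) == 1
                p_convert = np.where(meth, rm.inappropriate_conversion,
                                     rm.conversion_efficiency)
                conv = rng.random(len(g_pos)) < p_convert
                seq[g_pos[conv]] = ord("A")
            if rm.error_rate > 0:
                err = np.nonzero(rng.random(length) < rm.error_rate)[0]
                if len(err):
                    shift = rng.integers(1, 4, size=len(err))
                    seq[err] = acgt[(base_index[seq[err]] + shift) % 4]
            q = rm.lowq_quality if rng.random() < rm.lowq_fraction else rm.base_quality
            read_id = f"{subject.id}:{hap}:{a}:{k}"
            reads.append(FastqRead(
                id=read_id,
                seq=seq.tobytes().decode(),
                quals=np.full(length, q, dtype=np.int16),
            ))
            truth_rows.append({
                "read_id": read_id,
                "subject_id": subject.id,
                "allele": hap,
                "strand_space": space,
                "states": "".join("." if s < 0 else str(s) for s in states),
            })
    return reads, truth_rows


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    reference: AmpliconReference
    subjects: list
    reads: list
    read_truth: pd.DataFrame
    config: SimulationConfig

    def subject_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.id, "group": s.group, "sex": s.sex,
                "age": round(s.age, 2), "education": s.education,
                "smoking": s.smoking,
                "diplotype": "/".join(s.diplotype),
                "risk_allele_count": s.risk_allele_count,
                "cpg_snp_genotype": s.cpg_snp_genotype, "vntr": s.vntr,
                "SOB": s.SOB, "OC": s.OC, "ACE": s.ACE,
                "pers": round(s.pers, 6),
            }
            row.update({k: (round(v, 4) if isinstance(v, float) else v)
                        for k, v in s.phenotypes.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def truth_meth_frame(self) -> pd.DataFrame:
        names = [s.short_name for s in self.reference.sites]
        rows = []
        for s in self.subjects:
            for a, hap in enumerate(s.diplotype):
                rows.append({"subject_id": s.id, "allele_index": a, "allele": hap,
                             **dict(zip(names, np.round(s.truth_meth[a], 6)))})
        return pd.DataFrame(rows)

    def write(self, outdir) -> dict:
        """FASTQ + TSV truth tables + JSON manifest; returns the paths."""
        import hashlib
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reads": out / "reads.fastq",
            "subjects": out / "subjects.tsv",
            "truth_meth": out / "truth_methylation.tsv",
            "read_truth": out / "read_truth.tsv",
            "manifest": out / "manifest.json",
        }
        write_fastq(self.reads, paths["reads"])
        self.subject_frame().to_csv(paths["subjects"], sep="\t", index=False)
        self.truth_meth_frame().to_csv(paths["truth_meth"], sep="\t", index=False)
        self.read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
        cfg = json.dumps(asdict(self.config), default=str, sort_keys=True)
        manifest = {
            "seed": self.config.seed,
            "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
            "n_subjects": len(self.subjects),
            "n_reads": len(self.reads),
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2))
        return {k: str(v) for k, v in paths.items()}


def simulate_dataset(config: SimulationConfig,
                     reference: AmpliconReference | None = None,
                     with_reads: bool = True) -> SimulatedDataset:
    """Cohort + methylation truth + phenotypes (+ reads) under one seed."""
    reference = reference or synthetic_study_reference()
    rng = np.random.default_rng(config.seed)
    subjects = simulate_cohort(config, reference, rng)
    for s in subjects:
        s.truth_meth = simulate_methylation(
            s, config.site_models, reference, rng,
            default_cpg_meth=config.default_cpg_meth, cph_meth=config.cph_meth,
        )
        s.phenotypes = simulate_phenotypes(s, config.phenotype_model, reference, rng)
    reads, truth_rows = [], []
    if with_reads:
        for s in subjects:
            r, t = simulate_reads(s, reference, config.read_model, rng)
            reads += r
            truth_rows += t
    return SimulatedDataset(
        reference=reference,
        subjects=subjects,
        reads=reads,
        read_truth=pd.DataFrame(truth_rows),
        config=config,
    )
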