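"""Pipeline orchestration: simulate/load -> filter -> align -> call -> phase
-> score -> statistics -> mediation, with per-stage attrition logging and a
reproducible report.

Per-site genetic/environmental models follow the routing the analysis
prescribes: sites whose subject-level distribution passes (or is cubed into)
normality go to a bootstrap-BCa linear regression on allele-level rows
(haplotype contrasts + PERS + risk x PERS interaction); the near-bimodal
CpG-SNP goes to Kruskal-Wallis with Dunn post hoc plus a Spearman
correlation of PERS with DNAm conditioned on risk-allele carriage and
coverage.  Bonferroni families: 4 (VMS) for the site models, 6 (phenotypes)
for the phenotype models.  Depression (PANSS G6 >= 4) is analysed only when
enough subjects qualify (default minimum 10).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import quality_filter, align_reads, read_fastq
from .calling import conversion_qc, site_methylation
from .mediation import Mediation
from .phasing import build_allele_profiles, build_callset, subject_average, \
    subject_methylation_table
from .reference import load_reference
from .scores import PersWeights, detect_vms, pers_scores
from .simulate import SimulationConfig, simulate_dataset, synthetic_study_reference
from .stats import (BootstrapOLS, adjust_pvalues, conditional_spearman,
                    contingency_chisq, hwe_test, kruskal_dunn, normality_gate,
                    stepwise_select)

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "write_report"]

PHENOTYPES = ("verbal_fluency", "episodic_verbal_memory", "cognitive_flexibility",
              "cognitive_inhibition", "working_memory", "SIB")


class StageError(RuntimeError):
    def __init__(self, stage, err):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {err}")


@dataclass
class RunConfig:
    outdir: str = "allelemeth_out"
    seed: int = 0
    # thresholds
    min_quality: float = 30.0
    min_depth: int = 5
    vms_low: float = 0.20
    vms_high: float = 0.80
    identity_floor: float = 0.8
    # inference
    bootstrap_b: int = 1000
    vms_family: int = 4
    phenotype_family: int = 6
    depression_min_n: int = 10
    # inputs: either simulate (config) or file paths
    simulate: SimulationConfig | None = None
    reference_fasta: str | None = None
    annotation_json: str | None = None
    reads_fastq: str | None = None
    subjects_tsv: str | None = None
    # toggles
    run_stats: bool = True
    run_mediation: bool = True

    def __post_init__(self):
        if not (0 <= self.vms_low <= self.vms_high <= 1):
            raise ValueError("VMS bounds must satisfy 0 <= low <= high <= 1")
        if self.min_depth < 1 or self.min_quality < 0:
            raise ValueError("invalid thresholds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim) if isinstance(sim, dict) \
                else SimulationConfig()
        return cfg

    def sha256(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class AnalysisReport:
    qc: dict = field(default_factory=dict)
    vms: list = field(default_factory=list)
    site_models: list = field(default_factory=list)
    group_model: dict | None = None
    phenotype_models: list = field(default_factory=list)
    mediation: dict | None = None
    vntr: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return str(x)


def _regression_rows(results, model_label, family=None):
    frame = results.to_frame().reset_index(names="term")
    frame.insert(0, "model", model_label)
    if family:
        frame["p_bonf"] = adjust_pvalues(frame["p_boot"].fillna(1.0), family)
    return frame.to_dict("records")


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute all stages; any failure halts with a stage-labelled error."""
    report = AnalysisReport()
    report.provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "bootstrap_B": config.bootstrap_b,
    }

    # ---- stage: inputs ---------------------------------------------------
    try:
        if config.simulate is not None:
            dataset = simulate_dataset(config.simulate, synthetic_study_reference())
            reference = dataset.reference
            reads = dataset.reads
            subjects = dataset.subject_frame().set_index("subject_id")
        else:
            if not (config.reference_fasta and config.annotation_json
                    and config.reads_fastq and config.subjects_tsv):
                raise ValueError("either simulate or all four input paths required")
            reference = load_reference(config.reference_fasta, config.annotation_json)
            reads = read_fastq(config.reads_fastq)
            subjects = pd.read_csv(config.subjects_tsv, sep="\t") \
                .set_index("subject_id")
    except Exception as e:  # noqa: BLE001
        raise StageError("inputs", e) from e

    # ---- stage: filter + align + call + phase ----------------------------
    try:
        kept, fstats = quality_filter(reads, config.min_quality)
        aligned, rejected = align_reads(kept, reference,
                                        identity_floor=config.identity_floor)
        callsets = [build_callset(a, reference, subject_id=a.read_id.split(":")[0])
                    for a in aligned]
        qc = conversion_qc(callsets, reference)
        by_subject: dict[str, list] = {}
        for cs in callsets:
            by_subject.setdefault(cs.subject_id, []).append(cs)
        subject_meths, allele_rows, depth_failures = [], [], 0
        for sid, group in sorted(by_subject.items()):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                profiles, diplotype = build_allele_profiles(
                    group, sid, reference, min_depth=config.min_depth
                )
            if not profiles:
                continue
            depth_failures += sum(not p.passes_depth for p in profiles)
            passing = [p for p in profiles if p.passes_depth]
            if not passing:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                subject_meths.append(subject_average(profiles, diplotype, reference))
            for p in passing:
                for _, r in p.sites.iterrows():
                    allele_rows.append(
                        {"subject_id": sid, "allele": p.allele, "depth": p.depth,
                         "site": r["site"], "fraction": r["fraction"]}
                    )
        meth_table = subject_methylation_table(subject_meths) if subject_meths \
            else pd.DataFrame()
        allele_table = pd.DataFrame(allele_rows)
        report.qc = {
            "reads_total": len(reads),
            "reads_q30": fstats.retained,
            "reads_below_quality": fstats.discarded,
            "reads_unalignable": len(rejected),
            "reads_aligned": len(aligned),
            "alleles_below_depth": depth_failures,
            "subjects_with_methylation": len(subject_meths),
            "conversion_efficiency": qc.efficiency,
            "cph_flagged": qc.flagged,
        }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("methylation", e) from e

    if meth_table.empty or not config.run_stats:
        report.provenance["note"] = "no methylation data; QC-only report"
        return report

    # ---- stage: scores ---------------------------------------------------
    try:
        site_cols = [c for c in meth_table.columns if c != "coverage"]
        groups = subjects.reindex(meth_table.index)["group"]
        vms_report = detect_vms(meth_table[site_cols], config.vms_low,
                                config.vms_high, group=groups)
        report.vms = vms_report.table.to_dict("records")
        vms_sites = vms_report.vms_sites
        if {"SOB", "OC", "ACE"}.issubset(subjects.columns) \
                and "pers" not in subjects.columns:
            subjects["pers"] = pers_scores(subjects, PersWeights())
    except Exception as e:  # noqa: BLE001
        raise StageError("scores", e) from e

    # ---- stage: per-site genetic/environmental models --------------------
    try:
        patients = subjects[subjects["group"] == "patient"]
        pat_alleles = allele_table[allele_table["subject_id"].isin(patients.index)]
        site_rows = []
        m = config.vms_family
        for site in vms_sites:
            sub = pat_alleles[pat_alleles["site"] == site].copy()
            if sub.empty or sub["subject_id"].nunique() < 10:
                continue
            sub["pers"] = sub["subject_id"].map(patients["pers"]).astype(float)
            sub["risk"] = (sub["allele"] == "TGT").astype(float)
            subject_vals = meth_table[site].dropna()
            pat_vals = subject_vals[subject_vals.index.isin(patients.index)]
            gate = normality_gate(pat_vals.to_numpy()) if len(pat_vals) >= 8 else None
            if gate is not None and gate.normal:
                y = sub["fraction"].to_numpy()
                if gate.transform == "cube":
                    y = y**3
                design = pd.DataFrame({
                    "hap_GAG": (sub["allele"] == "GAG").astype(float),
                    "hap_TGG": (sub["allele"] == "TGG").astype(float),
                    "pers": sub["pers"],
                    "risk_x_pers": sub["risk"] * sub["pers"],
                })
                res = BootstrapOLS(y, design, B=config.bootstrap_b,
                                   seed=config.seed).fit()
                for row in _regression_rows(res, f"{site} ~ haplotype+PERS+interaction",
                                            family=m):
                    row.update({"site": site, "route": "ols_bca",
                                "transform": gate.transform})
                    site_rows.append(row)
            else:
                kw, dunn = kruskal_dunn(sub["fraction"], sub["allele"])
                site_rows.append({
                    "site": site, "route": "kruskal_dunn", "model": "kruskal",
                    "term": "haplotype", "beta": np.nan, "statistic": kw.statistic,
                    "p_boot": kw.p, "p_bonf": float(adjust_pvalues([kw.p], m)[0]),
                    "dunn": dunn.to_dict("records"),
                })
                sub_subj = sub.groupby("subject_id").agg(
                    fraction=("fraction", "mean")).join(patients[["pers"]])
                sub_subj["risk_count"] = patients["risk_allele_count"]
                sub_subj["coverage"] = meth_table["coverage"]
                sub_subj = sub_subj.dropna()
                if len(sub_subj) > 5 and np.ptp(sub_subj["fraction"]) > 0:
                    sp = conditional_spearman(
                        sub_subj["pers"], sub_subj["fraction"],
                        sub_subj[["risk_count", "coverage"]].to_numpy(),
                    )
                    site_rows.append({
                        "site": site, "route": "kruskal_dunn",
                        "model": "spearman(PERS, DNAm | risk, coverage)",
                        "term": "pers", "beta": sp.statistic, "p_boot": sp.p,
                        "p_bonf": float(adjust_pvalues([sp.p], m)[0]),
                    })
        report.site_models = site_rows
    except Exception as e:  # noqa: BLE001
        raise StageError("site_models", e) from e

    # ---- stage: diagnosis model (stepwise logistic on the VMS) -----------
    try:
        dd = meth_table[site_cols].join(subjects[["group", "sex", "age"]])
        dd["coverage"] = meth_table["coverage"]
        dd = dd.dropna(subset=vms_sites)
        if dd["group"].nunique() == 2 and len(dd) >= 20:
            y = (dd["group"] == "patient").astype(float)
            forced = pd.DataFrame({
                "sex_F": (dd["sex"] == "F").astype(float),
                "age": dd["age"].astype(float),
                "coverage": dd["coverage"].astype(float),
            })
            sw = stepwise_select(y, dd[vms_sites], forced, model="logit")
            report.group_model = {
                "selected": sw.selected, "path": sw.path,
                "terms": {t: float(b) for t, b in
                          zip(sw.exog.columns, sw.results.params)},
            }
    except Exception as e:  # noqa: BLE001
        raise StageError("group_model", e) from e

    # ---- stage: phenotype models -----------------------------------------
    try:
        pheno_rows = []
        pd_meth = meth_table.loc[meth_table.index.isin(patients.index)]
        analysed = list(PHENOTYPES)
        if "PANSS_G6" in patients.columns:
            n_dep = int((patients["PANSS_G6"] >= 4).sum())
            report.provenance["depression_eligible_n"] = n_dep
            if n_dep < config.depression_min_n:
                report.provenance["depression_dropped"] = True
        for phen in analysed:
            if phen not in patients.columns:
                continue
            joined = pd_meth[vms_sites].join(
                patients[[phen, "sex", "age", "education"]]).dropna()
            if len(joined) < 20:
                continue
            y = joined[phen].astype(float)
            forced = pd.DataFrame({
                "sex_F": (joined["sex"] == "F").astype(float),
                "age": joined["age"].astype(float),
            })
            if phen != "SIB":
                forced["tertiary"] = (joined["education"] == "tertiary").astype(float)
            model = "logit" if phen == "SIB" else "ols"
            sw = stepwise_select(y.to_numpy(), joined[vms_sites], forced, model=model)
            row = {"phenotype": phen, "selected": sw.selected, "path": sw.path}
            if sw.selected and model == "ols":
                res = BootstrapOLS(y.to_numpy(), sw.exog, add_constant=False,
                                   B=config.bootstrap_b, seed=config.seed).fit()
                row["terms"] = _regression_rows(res, phen,
                                                family=config.phenotype_family)
            pheno_rows.append(row)
        report.phenotype_models = pheno_rows
    except Exception as e:  # noqa: BLE001
        raise StageError("phenotypes", e) from e

    # ---- stage: mediation ------------------------------------------------
    try:
        if config.run_mediation:
            mediator_site = next((s for s in vms_sites if "SNP" in s), None)
            if mediator_site and "verbal_fluency" in patients.columns:
                joined = pd_meth[[mediator_site]].join(
                    patients[["verbal_fluency", "risk_allele_count", "sex",
                              "age", "education"]]).dropna()
                if len(joined) >= 20 and np.ptp(joined[mediator_site]) > 0:
                    conf = pd.DataFrame({
                        "sex_F": (joined["sex"] == "F").astype(float),
                        "age": joined["age"].astype(float),
                        "tertiary": (joined["education"] == "tertiary").astype(float),
                    })
                    med = Mediation(
                        joined["verbal_fluency"], joined["risk_allele_count"],
                        joined[mediator_site], conf,
                        B=config.bootstrap_b, seed=config.seed,
                    ).fit()
                    report.mediation = {
                        "outcome": "verbal_fluency", "mediator": mediator_site,
                        "a": med.a, "b": med.b,
                        "effects": med.to_frame().to_dict("records"),
                    }
    except Exception as e:  # noqa: BLE001
        raise StageError("mediation", e) from e

    # ---- stage: VNTR -----------------------------------------------------
    try:
        if "vntr" in subjects.columns:
            vntr = {}
            for grp, sub in subjects.groupby("group"):
                counts = sub["vntr"].value_counts()
                trip = (int(counts.get("V2V2", 0)), int(counts.get("V2V3", 0)),
                        int(counts.get("V3V3", 0)))
                h = hwe_test(trip)
                vntr[f"hwe_{grp}"] = {"chi2": h.statistic, "p": h.p,
                                      "v2_freq": h.extra["allele_freq"],
                                      "counts": trip}
            tab = pd.crosstab(subjects["group"], subjects["vntr"])
            if tab.shape == (2, 3) and (tab.sum(axis=0) > 0).all():
                chi = contingency_chisq(tab.to_numpy())
                vntr["genotype_freq_chi2"] = {"chi2": chi.statistic,
                                              "df": chi.df, "p": chi.p}
            report.vntr = vntr
    except Exception as e:  # noqa: BLE001
        raise StageError("vntr", e) from e

    # keep stage outputs for write_report
    report.provenance["n_subjects"] = len(subjects)
    report._meth_table = meth_table  # type: ignore[attr-defined]
    report._allele_table = allele_table  # type: ignore[attr-defined]
    report._subjects = subjects  # type: ignore[attr-defined]
    return report


def write_report(report: AnalysisReport, outdir) -> dict:
    """Persist the report: JSON + TSV matrices + human-readable summary."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"report": out / "report.json", "summary": out / "summary.txt"}
    paths["report"].write_text(report.to_json())
    for name, attr in (("subject_methylation", "_meth_table"),
                       ("allele_methylation", "_allele_table"),
                       ("subjects", "_subjects")):
        table = getattr(report, attr, None)
        if table is not None and len(table):
            p = out / f"{name}.tsv"
            table.to_csv(p, sep="\t")
            paths[name] = p
    lines = ["allelemeth analysis summary", "=" * 30, "", "QC:"]
    for k, v in report.qc.items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append(f"VMS ({len([r for r in report.vms if r.get('vms_flag')])} flagged):")
    for r in report.vms:
        if r.get("vms_flag"):
            lines.append(f"  {r['site']}: mean {r['mean']:.3f}")
    if report.mediation:
        lines.append("")
        lines.append(f"Mediation ({report.mediation['outcome']} via "
                     f"{report.mediation['mediator']}):")
        for e in report.mediation["effects"]:
            lines.append(
                f"  {e['effect']}: beta {e['beta']:.3f} "
                f"[{e['ci_low']:.3f}, {e['ci_high']:.3f}] p={e['p']}"
            )
    lines.append("")
    lines.append(f"provenance: {report.provenance}")
    paths["summary"].write_text("\n".join(lines) + "\n")
    return {k: str(v) for k, v in paths.items()}
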