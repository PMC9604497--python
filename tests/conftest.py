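import numpy as np
import pytest
from hypothesis import settings

from allelemeth.reference import build_reference
from allelemeth.simulate import (SimulationConfig, simulate_dataset,
                                 synthetic_study_reference)

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


def make_small_reference(seed: int = 5, length: int = 160, start: int = 1001):
    """A miniature amplicon with the same SNP/haplotype structure as the
    study locus, for fast unit tests."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length, p=[0.3, 0.2, 0.2, 0.3]).tolist()
    marker_offsets = (30, 70, 110)
    cpg_snp_offset = 140
    for off, base in zip(marker_offsets, "TGT"):
        seq[off] = base
        if seq[off - 1] == "C":
            seq[off - 1] = "A"
    seq[cpg_snp_offset:cpg_snp_offset + 2] = ["C", "G"]
    seq[20:22] = ["C", "G"]  # guarantee at least one ordinary CpG
    annotation = {
        "name": "mini", "chrom": "chrT", "start": start,
        "end": start + length - 1,
        "snps": [
            {"id": "m1", "coord": start + marker_offsets[0], "alleles": ["T", "G"]},
            {"id": "m2", "coord": start + marker_offsets[1], "alleles": ["G", "A"]},
            {"id": "m3", "coord": start + marker_offsets[2], "alleles": ["T", "G"]},
            {"id": "cs", "coord": start + cpg_snp_offset, "alleles": ["C", "T"],
             "role": "cpg_snp"},
        ],
        "haplotypes": [
            {"label": "TGT", "is_risk": True, "cpg_snp_allele": "C"},
            {"label": "GAG", "cpg_snp_allele": "T"},
            {"label": "TGG", "cpg_snp_allele": "T"},
        ],
    }
    return build_reference("".join(seq), annotation)


@pytest.fixture(scope="session")
def study_ref():
    return synthetic_study_reference()


@pytest.fixture(scope="session")
def small_ref():
    return make_small_reference()


@pytest.fixture(scope="session")
def small_dataset(study_ref):
    """Shared small cohort with reads at the default error model."""
    cfg = SimulationConfig(n_patients=6, n_controls=4, seed=3)
    return simulate_dataset(cfg, study_ref)


@pytest.fixture(scope="session")
def clean_dataset(study_ref):
    """Error-free, fully efficient reads: downstream calls equal latent truth."""
    cfg = SimulationConfig(n_patients=4, n_controls=2, seed=11)
    cfg.read_model.error_rate = 0.0
    cfg.read_model.conversion_efficiency = 1.0
    cfg.read_model.inappropriate_conversion = 0.0
    return simulate_dataset(cfg, study_ref)


@pytest.fixture(scope="session")
def processed(small_dataset):
    """Aligned callsets for the shared cohort."""
    from allelemeth.align import align_reads, quality_filter
    from allelemeth.phasing import build_callset

    kept, _ = quality_filter(small_dataset.reads)
    aligned, rejected = align_reads(kept, small_dataset.reference)
    callsets = [
        build_callset(a, small_dataset.reference,
                      subject_id=a.read_id.split(":")[0])
        for a in aligned
    ]
    return {"aligned": aligned, "rejected": rejected, "callsets": callsets}
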