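"""SNP masking, haplotype assignment, depth filtering and subject averaging."""

import numpy as np
import pandas as pd
import pytest

from allelemeth.calling import ReadCallSet, NA, M, U
from allelemeth.phasing import (AlleleMethylationProfile, assign_haplotype,
                                build_allele_profiles, build_callset,
                                conversion_image, genotype_read_snps,
                                infer_diplotype, subject_average,
                                subject_methylation_table)


# ---------------------------------------------------------------------------
# conversion-image masking
# ---------------------------------------------------------------------------

def test_conversion_images():
    assert conversion_image("C", "OT") == frozenset("CT")
    assert conversion_image("G", "OB") == frozenset("GA")
    assert conversion_image("C", "OB") == frozenset("C")
    assert conversion_image("T", "OT") == frozenset("T")


@pytest.mark.parametrize("alleles,space,masked", [
    (("G", "A"), "OB", True),   # G image {G,A} overlaps A
    (("G", "A"), "OT", False),
    (("T", "G"), "OT", False),
    (("C", "T"), "OT", True),   # C image {C,T} overlaps T: the CpG-SNP case
    (("C", "T"), "OB", False),
])
def test_masking_by_image_overlap(alleles, space, masked):
    img = [conversion_image(a, space) for a in alleles]
    assert bool(img[0] & img[1]) == masked


def test_genotyping_on_constructed_reads(small_ref):
    from allelemeth.align import FastqRead, align_read, collapse

    # unmethylated fully-converted OT read from the TGT (reference) allele
    seq = collapse(small_ref.allele_seq("TGT"), "OT")
    read = FastqRead("r", seq, np.full(len(seq), 40, dtype=np.int16))
    aln = align_read(read, small_ref, "OT", identity_floor=0.0)
    calls = genotype_read_snps(aln, small_ref)
    assert calls["m1"] == "T" and calls["m2"] == "G" and calls["m3"] == "T"
    assert calls["cs"] == "masked"  # C/T conversion-masked in OT space
    # same allele seen in OB space: m2 (G/A) masked, CpG-SNP readable as C
    seq = collapse(small_ref.allele_seq("TGT"), "OB")
    read = FastqRead("r2", seq, np.full(len(seq), 40, dtype=np.int16))
    aln = align_read(read, small_ref, "OB", identity_floor=0.0)
    calls = genotype_read_snps(aln, small_ref)
    assert calls["m2"] == "masked" and calls["cs"] == "C"


# ---------------------------------------------------------------------------
# haplotype assignment
# ---------------------------------------------------------------------------

def test_assignment_requires_unique_consistency(small_ref):
    assert assign_haplotype({"m1": "T", "m2": "G", "m3": "T"}, small_ref) == "TGT"
    # TGT and TGG both consistent -> unassigned
    assert assign_haplotype({"m1": "T", "m2": "masked", "m3": "masked"},
                            small_ref) is None
    # markers 1 and 3 suffice: (T, T) is TGT only
    assert assign_haplotype({"m1": "T", "m2": "masked", "m3": "T"},
                            small_ref) == "TGT"
    assert assign_haplotype({"m1": None, "m2": None, "m3": None}, small_ref) is None
    # inconsistent with all catalogue haplotypes
    assert assign_haplotype({"m1": "G", "m2": "G", "m3": "G"}, small_ref) is None


def test_phasing_accuracy_against_truth(small_dataset, processed):
    truth = small_dataset.read_truth.set_index("read_id")["allele"]
    assigned = [cs for cs in processed["callsets"] if cs.haplotype]
    correct = sum(cs.haplotype == truth[cs.read_id] for cs in assigned)
    assert len(assigned) / len(processed["callsets"]) > 0.9
    assert correct / len(assigned) >= 0.99


# ---------------------------------------------------------------------------
# allele profiles and the depth floor
# ---------------------------------------------------------------------------

def _callset(ref, hap, m_flags, rid):
    calls = np.full(len(ref.sites), NA, dtype=np.int8)
    for i, flag in enumerate(m_flags):
        calls[i] = M if flag else U
    return ReadCallSet(read_id=rid, strand_space="OT", calls=calls,
                       haplotype=hap, subject_id="s1")


def test_depth_floor_excludes_thin_alleles(small_ref):
    sets = [_callset(small_ref, "TGT", [1], f"a{i}") for i in range(10)]
    sets += [_callset(small_ref, "GAG", [0], f"b{i}") for i in range(4)]
    with pytest.warns(UserWarning, match="floor"):
        profiles, diplotype = build_allele_profiles(sets, "s1", small_ref,
                                                    min_depth=5)
    assert diplotype == ("GAG", "TGT")
    by = {p.allele: p for p in profiles}
    assert by["TGT"].passes_depth and by["TGT"].depth == 10
    assert not by["GAG"].passes_depth and by["GAG"].depth == 4


def test_homozygote_single_profile(small_ref):
    sets = [_callset(small_ref, "TGT", [1], f"a{i}") for i in range(8)]
    profiles, diplotype = build_allele_profiles(sets, "s1", small_ref)
    assert diplotype == ("TGT", "TGT")
    assert len(profiles) == 1 and profiles[0].depth == 8


def test_minority_labels_read_as_homozygote(small_ref):
    # 2 stray reads below the 20% threshold do not create a heterozygote
    sets = [_callset(small_ref, "TGT", [1], f"a{i}") for i in range(18)]
    sets += [_callset(small_ref, "GAG", [0], f"b{i}") for i in range(2)]
    _, diplotype = build_allele_profiles(sets, "s1", small_ref)
    assert diplotype == ("TGT", "TGT")


def test_no_read_contributes_twice(processed, small_dataset):
    callsets = processed["callsets"]
    by_subject = {}
    for cs in callsets:
        by_subject.setdefault(cs.subject_id, []).append(cs)
    for sid, group in by_subject.items():
        profiles, _ = build_allele_profiles(group, sid, small_dataset.reference)
        assert sum(p.depth for p in profiles) <= len(group)


def test_profile_fractions_match_truth_recount(clean_dataset):
    from allelemeth.align import align_reads, quality_filter

    ds = clean_dataset
    kept, _ = quality_filter(ds.reads)
    aligned, _ = align_reads(kept, ds.reference)
    callsets = [build_callset(a, ds.reference, subject_id=a.read_id.split(":")[0])
                for a in aligned]
    truth = ds.read_truth.set_index("read_id")
    subj = callsets[0].subject_id
    group = [cs for cs in callsets if cs.subject_id == subj]
    profiles, _ = build_allele_profiles(group, subj, ds.reference)
    names = [s.short_name for s in ds.reference.sites]
    for p in profiles:
        reads = [cs for cs in group if cs.haplotype == p.allele]
        for _, row in p.sites.iterrows():
            i = names.index(row["site"])
            latent = [int(truth.loc[cs.read_id, "states"][i])
                      for cs in reads if cs.calls[i] != NA]
            assert row["fraction"] == pytest.approx(np.mean(latent))


# ---------------------------------------------------------------------------
# subject-level averaging
# ---------------------------------------------------------------------------

def _profile(ref, allele, fracs, depth=10):
    rows = [{"site": s, "group": "all", "m_count": int(round(f * 10)),
             "total": 10, "fraction": f} for s, f in fracs.items()]
    frame = pd.DataFrame(rows, columns=["site", "group", "m_count", "total",
                                        "fraction"])
    return AlleleMethylationProfile("s1", allele, frame, depth, depth >= 5)


def test_heterozygote_average(small_ref):
    site = next(s.short_name for s in small_ref.sites
                if s.context == "CpG" and not s.is_cpg_snp)
    profiles = [_profile(small_ref, "TGT", {site: 0.8}),
                _profile(small_ref, "GAG", {site: 0.4})]
    sm = subject_average(profiles, ("TGT", "GAG"), small_ref)
    assert sm.values[site] == pytest.approx(0.6)
    assert sm.coverage == 20


def test_cpg_snp_structural_zero_rule(small_ref):
    snp_site = next(s.short_name for s in small_ref.sites if s.is_cpg_snp)
    profiles = [_profile(small_ref, "TGT", {snp_site: 0.9}),
                _profile(small_ref, "GAG", {})]
    sm = subject_average(profiles, ("TGT", "GAG"), small_ref)
    assert sm.values[snp_site] == pytest.approx(0.45)  # (0.9 + 0) / 2
    # T/T homozygote: structurally zero
    sm = subject_average([_profile(small_ref, "GAG", {})], ("GAG", "GAG"),
                         small_ref)
    assert sm.values[snp_site] == 0.0
    # behind the flag: T allele treated as missing instead
    profiles = [_profile(small_ref, "TGT", {snp_site: 0.9}),
                _profile(small_ref, "GAG", {})]
    sm = subject_average(profiles, ("TGT", "GAG"), small_ref,
                         t_allele_zero=False)
    assert sm.values[snp_site] == pytest.approx(0.9)


def test_homozygote_average_is_single_allele(small_ref):
    site = next(s.short_name for s in small_ref.sites
                if s.context == "CpG" and not s.is_cpg_snp)
    sm = subject_average([_profile(small_ref, "TGT", {site: 0.73})],
                         ("TGT", "TGT"), small_ref)
    assert sm.values[site] == pytest.approx(0.73)


def test_all_profiles_failing_depth_raises(small_ref):
    with pytest.raises(ValueError, match="depth floor"):
        subject_average([_profile(small_ref, "TGT", {}, depth=3)],
                        ("TGT", "TGT"), small_ref)


def test_subject_cpg_snp_distribution_ordered_by_risk_count(
        small_dataset, processed):
    """With complete linkage between the risk haplotype and the C allele, the
    subject-level CpG-SNP methylation is ordered TT < CT < CC."""
    ds = small_dataset
    by_subject = {}
    for cs in processed["callsets"]:
        by_subject.setdefault(cs.subject_id, []).append(cs)
    meths = []
    for sid, group in sorted(by_subject.items()):
        profiles, dip = build_allele_profiles(group, sid, ds.reference)
        meths.append(subject_average(profiles, dip, ds.reference))
    table = subject_methylation_table(meths)
    risk = {s.id: s.risk_allele_count for s in ds.subjects}
    table["risk"] = [risk[i] for i in table.index]
    means = table.groupby("risk")["CpG-SNP_5719"].mean()
    assert means.is_monotonic_increasing and means.iloc[0] < means.iloc[-1]
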