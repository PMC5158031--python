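import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triorecess.filters import (
    consequence_filter,
    filter_cascade,
    group_by_gene,
    maf_filter,
    tag_inheritance_proband_only,
    tag_inheritance_trio,
)
from triorecess.model import (
    DAMAGING_CLASSES,
    Consequence,
    GenotypeState,
    InheritanceModel,
    PipelineConfig,
)

from .conftest import random_trio_table, trio

HOM = GenotypeState.hom_alt
HET = GenotypeState.het
REF = GenotypeState.hom_ref
MISS = GenotypeState.missing


@pytest.mark.parametrize(
    "consequence,expected",
    [
        (Consequence.nonsense, True),
        (Consequence.missense, True),
        (Consequence.splice_site, True),
        (Consequence.small_deletion, True),
        (Consequence.small_insertion, True),
        (Consequence.other, False),
    ],
)
def test_consequence_gate(consequence, expected):
    assert consequence_filter(trio(consequence=consequence).variant) is expected


class TestMafFilter:
    def test_ultra_rare_passes(self):
        assert maf_filter(trio(pop_freqs={"AF_EXAC": 0.0000083}).variant, 0.005)

    def test_common_fails(self):
        assert not maf_filter(trio(pop_freqs={"AF_1KG": 0.01}).variant, 0.005)

    def test_boundary_is_inclusive(self):
        assert maf_filter(trio(pop_freqs={"AF_EXAC": 0.005}).variant, 0.005)

    def test_unknown_passes_but_any_common_db_disqualifies(self):
        assert maf_filter(trio(pop_freqs={}).variant, 0.005)
        v = trio(pop_freqs={"AF_EXAC": 0.0001, "AF_1KG": 0.02}).variant
        assert not maf_filter(v, 0.005)

    def test_toy_frequency_table(self):
        """Brute-force count over the ten-frequency toy table: the four
        frequencies at or below the inclusive bound pass, plus the unknown
        = five survivors."""
        freqs = [0.0, 0.001, 0.004, 0.005, 0.0051, 0.01, 0.05, 0.1, 0.5, None]
        variants = [
            trio(pos=i + 1, pop_freqs={} if f is None else {"AF_EXAC": f}).variant
            for i, f in enumerate(freqs)
        ]
        expected = sum(1 for f in freqs if f is None or f <= 0.005)
        assert expected == 5
        assert sum(maf_filter(v, 0.005) for v in variants) == expected


class TestTrioInheritance:
    def test_hom_child_het_parents_is_recessive(self):
        t = trio(HOM, HET, HET)
        assert tag_inheritance_trio(t, {}) is InheritanceModel.recessive_hom_trio

    def test_father_without_allele_fails_strict_model(self):
        t = trio(HOM, HET, REF)
        assert tag_inheritance_trio(t, {}) is InheritanceModel.none

    def test_missing_parent_non_disqualifying_by_default(self):
        t = trio(HOM, HET, MISS)
        assert tag_inheritance_trio(t, {}) is InheritanceModel.recessive_hom_trio
        assert (
            tag_inheritance_trio(t, {}, missing_parent_disqualifies=True)
            is InheritanceModel.none
        )

    def test_compound_het_requires_trans_configuration(self):
        a = trio(HET, HET, REF, pos=1, gene="G")
        b = trio(HET, REF, HET, pos=2, gene="G")
        grouping = {"G": [a, b]}
        assert tag_inheritance_trio(a, grouping) is InheritanceModel.compound_het_trio
        assert tag_inheritance_trio(b, grouping) is InheritanceModel.compound_het_trio
        # both variants maternal: cis-compatible, not compound het
        c = trio(HET, HET, REF, pos=3, gene="H")
        d = trio(HET, HET, REF, pos=4, gene="H")
        grouping = {"H": [c, d]}
        assert tag_inheritance_trio(c, grouping) is InheritanceModel.none


class TestProbandOnlyInheritance:
    def test_homozygous_regardless_of_father(self):
        t = trio(HOM, HET, REF)
        assert (
            tag_inheritance_proband_only(t, {}) is InheritanceModel.hom_proband_only
        )

    def test_het_singleton_is_none(self):
        t = trio(HET, REF, REF, gene="G")
        assert (
            tag_inheritance_proband_only(t, {"G": [t]}) is InheritanceModel.none
        )

    def test_two_hets_in_gene_qualify_without_phase(self):
        a = trio(HET, HET, HET, pos=1, gene="G")
        b = trio(HET, HET, HET, pos=2, gene="G")
        grouping = {"G": [a, b]}
        assert (
            tag_inheritance_proband_only(a, grouping)
            is InheritanceModel.comp_het_proband_only
        )

    def test_planted_panel_counts(self):
        """A 1000-variant panel with 35 planted proband-homozygous and 10
        planted same-gene het pairs yields exactly those survivor counts."""
        rng = np.random.default_rng(42)
        table = []
        pos = 1
        for i in range(35):  # planted homozygous, rare, damaging
            table.append(
                trio(HOM, HET, REF, pos=pos, gene=f"HOM{i}",
                     pop_freqs={"AF_EXAC": 1e-4},
                     consequence=Consequence.missense)
            )
            pos += 1
        for i in range(10):  # planted compound-het pairs
            for j in range(2):
                table.append(
                    trio(HET, HET, HET, pos=pos, gene=f"PAIR{i}",
                         pop_freqs={"AF_EXAC": 1e-4},
                         consequence=Consequence.nonsense)
                )
                pos += 1
        while len(table) < 1000:  # background failing a gate upstream
            common = rng.random() < 0.5
            table.append(
                trio(
                    GenotypeState(rng.choice(["hom_ref", "het"])), HET, HET,
                    pos=pos, gene=f"BG{pos}",
                    pop_freqs={"AF_1KG": 0.3} if common else {},
                    consequence=Consequence.missense if common else Consequence.other,
                )
            )
            pos += 1
        results = filter_cascade(table, PipelineConfig())
        n_hom = sum(
            r.proband_tag is InheritanceModel.hom_proband_only for r in results
        )
        n_pair_variants = sum(
            r.proband_tag is InheritanceModel.comp_het_proband_only for r in results
        )
        assert (n_hom, n_pair_variants // 2) == (35, 10)


# --- brute-force oracle ----------------------------------------------------


def brute_force_cascade(trios, config):
    """Independent literal evaluation of the filter definitions."""
    survivors = [
        t
        for t in trios
        if t.variant.consequence in DAMAGING_CLASSES
        and all(f <= config.maf_threshold for f in t.variant.pop_freqs.values())
    ]
    keys = {t.variant.key for t in survivors}

    def origin(t):
        m = t.mother.state in (HET, HOM)
        f = t.father.state in (HET, HOM)
        if t.mother.state is MISS or t.father.state is MISS:
            return None
        if m and not f:
            return "M"
        if f and not m:
            return "F"
        return None

    strict, proband = {}, {}
    for t in survivors:
        p = t.proband.state
        s = InheritanceModel.none
        if p is HOM:
            par_ok = []
            for st in (t.mother.state, t.father.state):
                par_ok.append(st is HET or (st is MISS and not
                                            config.missing_parent_disqualifies))
            if all(par_ok):
                s = InheritanceModel.recessive_hom_trio
        elif p is HET and t.variant.gene and origin(t) is not None:
            for other in survivors:
                if (
                    other.variant.gene == t.variant.gene
                    and other.variant.key != t.variant.key
                    and other.proband.state is HET
                    and origin(other) is not None
                    and origin(other) != origin(t)
                ):
                    s = InheritanceModel.compound_het_trio
                    break
        strict[t.variant.key] = s

        po = InheritanceModel.none
        if p is HOM:
            po = InheritanceModel.hom_proband_only
        elif p is HET and t.variant.gene:
            n = sum(
                1
                for o in survivors
                if o.variant.gene == t.variant.gene and o.proband.state is HET
            )
            if n >= 2:
                po = InheritanceModel.comp_het_proband_only
        proband[t.variant.key] = po
    return keys, strict, proband


@pytest.mark.parametrize("seed", range(25))
def test_cascade_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    table = random_trio_table(rng, int(rng.integers(5, 50)))
    config = PipelineConfig()
    keys, strict, proband = brute_force_cascade(table, config)
    for res in filter_cascade(table, config):
        k = res.trio.variant.key
        assert res.survives == (k in keys)
        if res.survives:
            assert res.strict_tag is strict[k]
            assert res.proband_tag is proband[k]


@settings(max_examples=60, deadline=None)
@given(
    freqs=st.lists(
        st.one_of(st.none(), st.floats(0, 1, allow_nan=False)), min_size=1,
        max_size=30,
    ),
    lo=st.floats(0, 1, allow_nan=False),
    hi=st.floats(0, 1, allow_nan=False),
)
def test_maf_threshold_monotonicity(freqs, lo, hi):
    """Lowering the threshold never grows the surviving set."""
    lo, hi = min(lo, hi), max(lo, hi)
    variants = [
        trio(pos=i + 1, pop_freqs={} if f is None else {"AF_EXAC": f}).variant
        for i, f in enumerate(freqs)
    ]
    passed_lo = {v.pos for v in variants if maf_filter(v, lo)}
    passed_hi = {v.pos for v in variants if maf_filter(v, hi)}
    assert passed_lo <= passed_hi


@pytest.mark.parametrize("seed", range(10))
def test_strict_candidates_subset_of_proband_only(seed):
    rng = np.random.default_rng(seed)
    table = random_trio_table(rng, 40)
    for res in filter_cascade(table, PipelineConfig()):
        if res.strict_tag is InheritanceModel.recessive_hom_trio:
            assert res.proband_tag is InheritanceModel.hom_proband_only
        if res.strict_tag is InheritanceModel.compound_het_trio:
            assert res.proband_tag is InheritanceModel.comp_het_proband_only


def test_gene_grouping_skips_unannotated_genes():
    t = trio(gene="")
    assert group_by_gene([t]) == {}
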