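"""The filtering cascade: stage semantics, trace telescoping, oracle
equivalence and planted-variant recovery."""

import numpy as np
import pytest

from famvar import (
    AnnotatedVariant,
    CascadeConfig,
    ContractError,
    Disposition,
    DomainError,
    Family,
    FunctionalClass,
    GenotypeCall,
    Individual,
    Mode,
    PopulationDatabase,
    Status,
    SyntheticConfig,
    VariantKey,
    Zygosity,
    filter_benign,
    filter_family_normal,
    filter_functional,
    filter_known,
    generate_callsets,
    quality_gate,
    run_cascade,
)
from famvar.cascade import FilterTrace


def _fam(statuses, fam_id="T"):
    return Family(
        fam_id,
        [Individual(f"{fam_id}{i}", fam_id, status=s) for i, s in enumerate(statuses, 1)],
    )


def _key(i):
    return VariantKey(f"chr{i % 22 + 1}", 1000 + i, "A", "G")


def _ann(key, fc=FunctionalClass.NONSYNONYMOUS_SNV, score=0.99):
    return AnnotatedVariant.make(key, "G", fc, score=score)


class TestQualityGate:
    @pytest.mark.parametrize(
        "depth,qual,kept", [(9, True, False), (10, True, True), (30, False, False)]
    )
    def test_depth_and_quality_thresholds(self, depth, qual, kept):
        trace = FilterTrace("u")
        calls = {"S": [GenotypeCall("S", _key(1), Zygosity.HET, depth, qual)]}
        out = quality_gate(calls, CascadeConfig(), trace)
        assert (_key(1) in out["S"]) is kept

    def test_identity_when_all_pass(self):
        trace = FilterTrace("u")
        calls = {
            "S": [GenotypeCall("S", _key(i), Zygosity.HET, 10 + i, True) for i in range(5)]
        }
        out = quality_gate(calls, CascadeConfig(), trace)
        assert out["S"] == {_key(i) for i in range(5)}
        assert trace.stage_counts == [("quality", 5, 0, 5)]

    def test_homref_and_missing_are_nonvariant(self):
        trace = FilterTrace("u")
        calls = {
            "S": [
                GenotypeCall("S", _key(1), Zygosity.HOM_REF, 50, True),
                GenotypeCall("S", _key(2), Zygosity.MISSING, 50, True),
                GenotypeCall("S", _key(3), Zygosity.HOM_ALT, 50, True),
            ]
        }
        out = quality_gate(calls, CascadeConfig(), trace)
        assert out["S"] == {_key(3)}
        assert trace.n_nonvariant_calls == 2
        assert trace.stage_counts[0][1] == 1  # only the variant-asserting call


class TestStages:
    def test_known_filter_is_set_difference(self):
        db = PopulationDatabase()
        for i in range(0, 10, 2):
            db.add(_key(i))
        sets = {"S": {_key(i) for i in range(10)}}
        trace = FilterTrace("u")
        out = filter_known(sets, db, trace)
        assert out["S"] == {_key(i) for i in range(1, 10, 2)}

    def test_known_filter_empty_db_is_identity(self):
        sets = {"S": {_key(i) for i in range(5)}}
        out = filter_known(sets, PopulationDatabase(), FilterTrace("u"))
        assert out == sets

    def test_family_normal_removes_family_wide(self):
        fam = _fam([Status.AFFECTED, Status.AFFECTED, Status.UNAFFECTED])
        shared = _key(1)
        sets = {"T1": {shared, _key(2)}, "T2": {shared}, "T3": {shared}}
        out = filter_family_normal(fam, sets, FilterTrace("u"))
        assert out == {"T1": {_key(2)}, "T2": set(), "T3": set()}

    def test_family_normal_spares_affected_only_variants(self):
        fam = _fam([Status.AFFECTED] * 5 + [Status.UNAFFECTED] * 2)
        v = _key(9)
        sets = {s: ({v} if i < 5 else set()) for i, s in enumerate(fam.sample_ids)}
        out = filter_family_normal(fam, sets, FilterTrace("u"))
        assert all(v in out[s] for s in fam.sample_ids[:5])

    def test_obligate_carrier_variants_not_subtracted(self):
        fam = _fam([Status.AFFECTED, Status.OBLIGATE_CARRIER, Status.UNAFFECTED])
        v = _key(4)
        sets = {"T1": {v}, "T2": {v}, "T3": set()}
        out = filter_family_normal(fam, sets, FilterTrace("u"))
        assert out["T1"] == {v} and out["T2"] == {v}

    def test_no_unaffected_members_is_identity(self):
        fam = _fam([Status.AFFECTED, Status.AFFECTED])
        sets = {"T1": {_key(1)}, "T2": {_key(2)}}
        assert filter_family_normal(fam, sets, FilterTrace("u")) == sets

    def test_family_normal_in_proband_mode_is_contract_error(self):
        fam = _fam([Status.AFFECTED])
        with pytest.raises(ContractError):
            filter_family_normal(fam, {"T1": set()}, FilterTrace("u"), mode=Mode.PROBAND)

    def test_functional_filter_removes_synonymous_keeps_stopgain(self):
        ann = {
            _key(1): _ann(_key(1), FunctionalClass.SYNONYMOUS_SNV, None),
            _key(2): _ann(_key(2), FunctionalClass.STOPGAIN, None),
        }
        out = filter_functional({"S": {_key(1), _key(2)}}, ann, FilterTrace("u"))
        assert out["S"] == {_key(2)}

    def test_functional_filter_errors_on_unannotated(self):
        with pytest.raises(DomainError, match="unannotated"):
            filter_functional({"S": {_key(1)}}, {}, FilterTrace("u"))

    def test_benign_filter(self):
        ann = {
            _key(1): _ann(_key(1), score=0.2),     # benign -> removed
            _key(2): _ann(_key(2), score=0.62),    # possibly damaging -> kept
            _key(3): _ann(_key(3), FunctionalClass.SPLICING, None),  # unscored -> kept
        }
        trace = FilterTrace("u")
        out = filter_benign({"S": {_key(1), _key(2), _key(3)}}, ann, trace)
        assert out["S"] == {_key(2), _key(3)}
        assert trace.records[("S", _key(1))] == Disposition.REMOVED_BENIGN.value


# ---------------------------------------------------------------------------
# Randomized whole-cascade checks against a first-principles oracle
# ---------------------------------------------------------------------------


def _random_problem(rng, n_variants=40, n_members=5):
    statuses = [Status.AFFECTED] * (n_members - 2) + [Status.UNAFFECTED] * 2
    fam = _fam(statuses, "R")
    keys = [_key(i) for i in range(n_variants)]
    db = PopulationDatabase()
    ann = {}
    for k in keys:
        if rng.random() < 0.3:
            db.add(k)
        u = rng.random()
        if u < 0.4:
            ann[k] = _ann(k, FunctionalClass.NONSYNONYMOUS_SNV, round(rng.random(), 3))
        elif u < 0.6:
            ann[k] = _ann(k, FunctionalClass.SYNONYMOUS_SNV, None)
        elif u < 0.8:
            ann[k] = _ann(k, FunctionalClass.SPLICING, None)
        else:
            ann[k] = _ann(k, FunctionalClass.OTHER, None)
    calls = {}
    for s in fam.sample_ids:
        sample_calls = []
        for k in keys:
            zyg = rng.choice(
                [Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT, Zygosity.MISSING],
                p=[0.3, 0.4, 0.2, 0.1],
            )
            depth = int(rng.integers(0, 40))
            qual = bool(rng.random() < 0.9)
            sample_calls.append(GenotypeCall(s, k, zyg, depth, qual))
        calls[s] = sample_calls
    return fam, calls, db, ann


def _oracle_retained(fam, calls, db, ann, cfg):
    """Independent re-derivation of each disposition from first principles."""
    def passing(c):
        return (
            c.zygosity in (Zygosity.HET, Zygosity.HOM_ALT)
            and c.depth >= cfg.min_depth
            and (not cfg.require_qual_pass or c.qual_pass)
        )

    present = {s: {c.key for c in cs if passing(c)} for s, cs in calls.items()}
    unaffected_keys = set()
    if cfg.mode == Mode.FAMILY:
        for m in fam.members:
            if m.status == Status.UNAFFECTED:
                unaffected_keys |= present[m.sample_id]
    out = {}
    for s, keys in present.items():
        out[s] = {
            k for k in keys
            if k not in db
            and k not in unaffected_keys
            and ann[k].functional_class.value in
                ("nonsynonymous_snv", "splicing", "stopgain", "stoploss")
            and ann[k].bin.value != "benign"
        }
    return out


@pytest.mark.parametrize("seed", range(8))
def test_cascade_equals_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    fam, calls, db, ann = _random_problem(rng)
    cfg = CascadeConfig()
    retained, trace = run_cascade(calls, fam, db, ann, cfg)
    assert retained == _oracle_retained(fam, calls, db, ann, cfg)
    trace.check_telescoping()


@pytest.mark.parametrize("seed", range(5))
def test_known_and_family_normal_commute(seed):
    """Both stages are pure set subtractions, so swapping their order
    leaves the final sets unchanged."""
    rng = np.random.default_rng(100 + seed)
    fam, calls, db, ann = _random_problem(rng)
    cfg = CascadeConfig()
    sets0 = quality_gate(calls, cfg, FilterTrace("a"))

    t1, t2 = FilterTrace("b"), FilterTrace("c")
    order_a = filter_family_normal(fam, filter_known(dict(sets0), db, t1), t1)
    order_b = filter_known(filter_family_normal(fam, dict(sets0), t2), db, t2)
    assert order_a == order_b


def test_trace_telescopes_and_partitions(tiny_cohort):
    fam = tiny_cohort.families[0]
    retained, trace = run_cascade(
        tiny_cohort.family_calls[fam.family_id], fam,
        tiny_cohort.population, tiny_cohort.annotations,
    )
    trace.check_telescoping()
    # chained counts: out of stage k == in of stage k+1
    for (_, _, _, out_k), (_, in_k1, _, _) in zip(trace.stage_counts, trace.stage_counts[1:]):
        assert out_k == in_k1
    # every traced call has exactly one disposition; retained set matches
    n_retained = sum(
        1 for d in trace.records.values() if d == Disposition.RETAINED.value
    )
    assert n_retained == sum(len(s) for s in retained.values())
    assert trace.retained_sets() == {s: k for s, k in retained.items() if k}


class TestProbandMode:
    def test_proband_mode_rejects_multimember_family(self, tiny_cohort):
        fam = tiny_cohort.families[0]
        with pytest.raises(ContractError, match="single-member"):
            run_cascade(
                tiny_cohort.family_calls[fam.family_id], fam,
                tiny_cohort.population, tiny_cohort.annotations,
                CascadeConfig(mode=Mode.PROBAND),
            )

    def test_proband_mode_skips_family_normal(self):
        """A variant shared with an unaffected sibling in the same VCF is
        still retained for a proband: only population filtering applies."""
        pro = Family("P", [Individual("P", "P", status=Status.AFFECTED, is_proband=True)])
        v = _key(1)
        ann = {v: _ann(v)}
        calls = {"P": [GenotypeCall("P", v, Zygosity.HET, 30, True)]}
        retained, trace = run_cascade(
            calls, pro, PopulationDatabase(), ann, CascadeConfig(mode=Mode.PROBAND)
        )
        assert retained["P"] == {v}
        assert [s for s, *_ in trace.stage_counts] == [
            "quality", "known", "functional", "benign"
        ]


class TestRecovery:
    @pytest.mark.parametrize("seed", [3, 17, 91])
    def test_planted_variant_recovered_in_all_affected(self, seed):
        """Penetrance 1, phenocopy 0, zero genotyping error: the planted
        predisposition survives in every affected member and is the only
        variant carried by all of them."""
        cfg = SyntheticConfig(
            n_families=1, n_probands=0, n_common=60, n_family_private_benign=6,
            n_sporadic_deleterious=3, n_synonymous_novel=4,
            depth_dispersion=1e9, seed=seed,
        )
        cohort = generate_callsets(cfg)
        fam = cohort.families[0]
        retained, _ = run_cascade(
            cohort.family_calls[fam.family_id], fam,
            cohort.population, cohort.annotations,
        )
        (planted,) = cohort.truth.planted[fam.family_id]
        affected = [m.sample_id for m in fam.affected]
        assert all(planted in retained[s] for s in affected)
        union = set().union(*retained.values())
        sporadic = {
            k for k in union
            if cohort.truth.labels[k] == "sporadic_deleterious"
        }
        assert union == sporadic | {planted}
        if len(affected) >= 2:
            carried_by_all = set.intersection(*(retained[s] for s in affected))
            assert carried_by_all == {planted}

    def test_only_common_variants_yields_empty_retained(self):
        cfg = SyntheticConfig(
            n_families=1, n_probands=0, n_common=40, n_family_private_benign=0,
            n_planted_predisposition=0, n_sporadic_deleterious=0,
            n_synonymous_novel=0, depth_dispersion=1e9, seed=5,
        )
        cohort = generate_callsets(cfg)
        fam = cohort.families[0]
        retained, _ = run_cascade(
            cohort.family_calls[fam.family_id], fam,
            cohort.population, cohort.annotations,
        )
        assert all(not s for s in retained.values())
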