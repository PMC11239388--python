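import numpy as np
import pytest

from mrkit.exceptions import NoInstrumentsError
from mrkit.instruments import (
    ConfounderAnnotation,
    LdInfo,
    clump,
    f_statistic,
    filter_confounders,
    select_instruments,
)
from conftest import make_table
from oracles import clump_valid


@pytest.mark.parametrize(
    "beta,se,expected",
    [(0.1, 0.02, 25.0), (0.0, 0.1, 0.0), (-0.3, 0.1, 9.0)],
)
def test_f_statistic_direct_evaluation(beta, se, expected):
    assert f_statistic(beta, se) == pytest.approx(expected)


def test_f_statistic_rejects_nonpositive_se():
    with pytest.raises(ValueError):
        f_statistic(0.1, 0.0)


def test_clump_keeps_all_independent_snps():
    t = make_table([{"pos": 1000 * i} for i in range(3)])
    ld = LdInfo.identity(t.snp_ids.tolist())
    assert clump(t, ld) == sorted(t.snp_ids.tolist(), key=str)  # all retained


def test_clump_drops_the_less_significant_of_a_linked_pair():
    t = make_table(
        [
            {"pos": 1000, "pval": 1e-8},
            {"pos": 6000, "pval": 1e-6},
        ]
    )
    ld = LdInfo.from_pairs(["rs1", "rs2"], [("rs1", "rs2", 0.9)])
    assert clump(t, ld, r2_threshold=0.001) == ["rs1"]


def test_clump_matches_exhaustive_verification_on_block_structure(rng):
    # 6 SNPs on 2 chromosomes, block-diagonal r2 within each chromosome
    rows = []
    for i in range(6):
        rows.append(
            {"chrom": "1" if i < 3 else "2", "pos": 1000 + (i % 3) * 2000,
             "pval": float(rng.uniform(1e-9, 1e-4))}
        )
    t = make_table(rows)
    ids = t.snp_ids.tolist()
    r2 = np.eye(6)
    r2[0:3, 0:3] = 0.8
    r2[3:6, 3:6] = 0.8
    np.fill_diagonal(r2, 1.0)
    ld = LdInfo(ids, r2)
    retained = clump(t, ld, r2_threshold=0.001, window_kb=10)
    assert clump_valid(t.data, ld, retained, 0.001, 10)
    assert len(retained) == 2  # one index SNP per block


def test_clump_is_idempotent(rng):
    rows = [
        {"chrom": str(1 + i % 4), "pos": 1000 + (i // 4) * 3000,
         "pval": float(rng.uniform(1e-12, 1e-3))}
        for i in range(20)
    ]
    t = make_table(rows)
    ids = t.snp_ids.tolist()
    a = rng.uniform(0, 1, (20, 20))
    r2 = np.clip((a + a.T) / 2, 0, 1)
    np.fill_diagonal(r2, 1.0)
    ld = LdInfo(ids, r2)
    first = clump(t, ld, r2_threshold=0.3, window_kb=100)
    again = clump(t.subset(first), ld, r2_threshold=0.3, window_kb=100)
    assert again == first


def test_no_instruments_error_when_nothing_passes_p_threshold():
    t = make_table([{"pval": 0.5} for _ in range(10)])
    with pytest.raises(NoInstrumentsError):
        select_instruments(t, p_threshold=5e-6)


def test_single_strong_snp_selected_with_f_25():
    t = make_table([{"pval": 1e-8, "beta": 0.1, "se": 0.02}])
    inst = select_instruments(t, p_threshold=5e-6)
    assert inst.snp_ids == ["rs1"]
    assert inst.f_stats.iloc[0] == pytest.approx(25.0)


def test_select_matches_bruteforce_three_stage_filter(rng):
    # 200 SNPs in LD blocks of 4; oracle applies the three filters serially
    m = 200
    rows = []
    for i in range(m):
        rows.append(
            {
                "chrom": str(1 + (i // 40)),
                "pos": 1_000_000 + (i % 40) * 2000,
                "pval": float(10 ** rng.uniform(-12, -1)),
                "beta": float(rng.normal(0, 0.05)),
                "se": float(rng.uniform(0.005, 0.02)),
            }
        )
    t = make_table(rows)
    ids = t.snp_ids.tolist()
    r2 = np.eye(m)
    for b in range(m // 4):
        r2[b * 4:(b + 1) * 4, b * 4:(b + 1) * 4] = 0.5
    np.fill_diagonal(r2, 1.0)
    ld = LdInfo(ids, r2)
    p_thr, r2_thr, win, f_min = 5e-6, 0.001, 10_000, 10.0

    inst = select_instruments(t, p_thr, ld, r2_thr, win, f_min)

    passed = t.data[t.data["pval"] < p_thr]
    retained = clump(t.subset(passed["snp_id"].tolist()), ld, r2_thr, win)
    assert clump_valid(passed, ld, retained, r2_thr, win)
    expect = [
        sid for sid in retained
        if f_statistic(
            float(passed.set_index("snp_id").loc[sid, "beta"]),
            float(passed.set_index("snp_id").loc[sid, "se"]),
        ) >= f_min
    ]
    assert inst.snp_ids == expect
    # retained + excluded partition the input
    excluded = {sid for sid, _ in inst.exclusions}
    assert excluded | set(inst.snp_ids) == set(ids)
    assert excluded.isdisjoint(inst.snp_ids)


def test_lower_p_threshold_never_increases_retained_count(rng):
    rows = [
        {"pval": float(10 ** rng.uniform(-10, 0)), "pos": 1_000_000 * (i + 1)}
        for i in range(50)
    ]
    t = make_table(rows)
    counts = []
    for thr in (1e-2, 1e-4, 5e-6, 5e-8):
        try:
            counts.append(select_instruments(t, p_threshold=thr).n_instruments)
        except NoInstrumentsError:
            counts.append(0)
    assert counts == sorted(counts, reverse=True)


def _instrument_set(n):
    t = make_table([{"pos": 1_000_000 * (i + 1), "pval": 1e-9} for i in range(n)])
    return select_instruments(t, p_threshold=5e-6)


def test_confounder_filter_101_minus_45_keeps_56():
    inst = _instrument_set(101)
    flagged_traits = (
        ["BMI"] * 28 + ["weight"] * 3 + ["obesity"] + ["waist circumference"]
        + ["arthropathies"] * 6 + ["BMD"] * 2 + ["vitamin D"] * 2 + ["smoking"] * 2
    )
    ann = ConfounderAnnotation.from_records(
        [(inst.snp_ids[i], trait) for i, trait in enumerate(flagged_traits)]
    )
    out = filter_confounders(inst, ann, sorted(set(flagged_traits)))
    assert inst.n_instruments == 101
    assert out.n_instruments == 56
    assert sum(1 for _, r in out.exclusions if r.startswith("confounder:")) == 45


def test_confounder_filter_with_disjoint_traits_is_identity():
    inst = _instrument_set(5)
    ann = ConfounderAnnotation.from_records([("rs1", "height")])
    out = filter_confounders(inst, ann, ["BMI"])
    assert out.snp_ids == inst.snp_ids


def test_snp_flagged_for_two_traits_dropped_once_with_two_exclusion_rows():
    inst = _instrument_set(3)
    ann = ConfounderAnnotation.from_records([("rs1", "BMI"), ("rs1", "smoking")])
    out = filter_confounders(inst, ann, ["BMI", "smoking"])
    assert out.n_instruments == 2
    conf_rows = [e for e in out.exclusions if e[0] == "rs1"]
    assert sorted(conf_rows) == [("rs1", "confounder:BMI"), ("rs1", "confounder:smoking")]
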