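"""Paracopy statistics, table rendering and sequence-logo math."""

import math
import random

import numpy as np
import pytest

from npmine.models import TaxonGroup, FamilyAssignment
from npmine.stats import (
    ParacopySummary,
    build_logo,
    format_mean,
    pad_cterm,
    presence_matrix,
    render_cell,
    s_n,
)

LOG2_20 = math.log2(20)


def oracle_sn(values):
    """Two-pass brute-force uncorrected standard deviation."""
    mean = sum(values) / len(values)
    return math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))


def test_sn_witness_distinguishes_denominator():
    """{3,4} has S_N exactly 0.5 only with the N (not N-1) denominator."""
    assert s_n([3, 4]) == pytest.approx(0.5)
    assert np.std([3, 4], ddof=1) != pytest.approx(0.5)


def test_sn_matches_bruteforce_on_1000_samples():
    rng = random.Random(0)
    for _ in range(1000):
        vals = [rng.randint(1, 25) for _ in range(rng.randint(1, 12))]
        assert s_n(vals) == pytest.approx(oracle_sn(vals), abs=1e-12)
        if len(vals) >= 2:
            assert s_n(vals) <= np.std(vals, ddof=1) + 1e-12


def test_render_cells():
    mk = lambda mean, sn, n=2: ParacopySummary("F", "T", n, mean, sn)
    assert render_cell(mk(3.5, 0.5)) == "3.5 ± 0.5"
    assert render_cell(mk(4.0, 0.0)) == "4 ± 0"
    assert render_cell(mk(2.0, 0.0)) == "2 ± 0"
    assert render_cell(mk(7.0, None, n=1)) == "7"
    assert render_cell(ParacopySummary("F", "T", 0, None, None, max_partial=20)) == "(≥20)"


def test_mean_formatting_matches_published_precision():
    assert format_mean(38 / 9) == "4.2"
    assert format_mean(1.75) == "1.75"
    assert format_mean(46 / 3) == "15.3"  # half-up, not bankers' rounding
    assert format_mean(11.6) == "11.6"
    assert format_mean(12.0) == "12"


def test_summary_semantics_full_single_partial(registry, panel_reports):
    _panel, _result, rep = panel_reports["Protura"]
    by_key = {(s.family, s.taxon): s for s in rep["paracopy_summaries"]}
    kinin = by_key[("kinin", "Protura")]
    assert kinin.n_full == 2 and kinin.s_n == pytest.approx(0.5)
    natalisin = by_key[("natalisin", "Protura")]
    assert natalisin.n_full == 3 and natalisin.s_n == pytest.approx(0.0)
    efla = by_key[("EFLa", "Protura")]
    assert efla.n_full == 0 and efla.max_partial == 18  # partial-only: max


def test_presence_matrix_absence_vs_missing():
    taxa = {"Diplura": ["d1", "d2"], "Collembola": ["c1"]}
    assignments = [
        FamilyAssignment("p1", "CCAP", [], 1, species="d1", taxon_group=TaxonGroup.DIPLURA),
        FamilyAssignment("p2", "CCAP", [], 1, species="d2", taxon_group=TaxonGroup.DIPLURA),
        FamilyAssignment("p3", "CCAP", [], 1, species="c1", taxon_group=TaxonGroup.COLLEMBOLA),
        FamilyAssignment("p4", "PDF", [], 1, species="c1", taxon_group=TaxonGroup.COLLEMBOLA),
        FamilyAssignment("p5", "unassigned", [], 0, species="c1", taxon_group=TaxonGroup.COLLEMBOLA),
    ]
    m = presence_matrix(assignments, taxa)
    assert m.loc["CCAP", "Diplura"] == 2  # present in all surveyed species
    assert m.loc["PDF", "Diplura"] == 0  # surveyed, absent
    assert m.loc["PDF", "Collembola"] == 1
    assert "Zygentoma" not in m.columns  # unsurveyed taxon: no column at all
    assert "unassigned" not in m.index


def test_empty_presence_matrix():
    m = presence_matrix([], {"Diplura": []})
    assert m.empty or (m.values == 0).all()


def test_logo_fully_conserved_column():
    logo = build_logo(["F", "F", "F", "F"])
    assert logo.info[0] == pytest.approx(LOG2_20)
    assert logo.heights[0].sum() == pytest.approx(LOG2_20)


def test_logo_uniform_column_zero_info():
    logo = build_logo(list("ACDEFGHIKLMNPQRSTVWY"))
    assert logo.info[0] == pytest.approx(0.0)


def test_logo_half_split_hand_value():
    """A {0.5 F, 0.5 Y} column carries log2(20) - 1 ≈ 3.3219 bits, letter
    heights 1.6610 each."""
    logo = build_logo(["F"] * 10 + ["Y"] * 10)
    assert logo.info[0] == pytest.approx(LOG2_20 - 1, abs=1e-4)
    f = logo.heights[0][list("ACDEFGHIKLMNPQRSTVWY").index("F")]
    y = logo.heights[0][list("ACDEFGHIKLMNPQRSTVWY").index("Y")]
    assert f == pytest.approx((LOG2_20 - 1) / 2, abs=1e-4)
    assert y == pytest.approx(f)


def test_logo_heights_sum_to_info_and_bounds():
    rng = random.Random(4)
    seqs = ["".join(rng.choice("ACDEFGHIKLMNPQRSTVWY-") for _ in range(12))
            for _ in range(30)]
    logo = build_logo(seqs)
    for i in range(logo.length):
        assert 0.0 <= logo.info[i] <= LOG2_20 + 1e-12
        assert logo.heights[i].sum() == pytest.approx(logo.info[i])
        nz = logo.freqs[i][logo.freqs[i] > 0]
        if nz.size:
            assert nz.sum() == pytest.approx(1.0)


def test_logo_info_decreases_as_column_flattens():
    """Majorization: nested distributions with progressively flatter columns
    have monotonically non-increasing information."""
    pools = ["F" * 12, "F" * 9 + "Y" * 3, "F" * 6 + "Y" * 6,
             "F" * 6 + "Y" * 3 + "W" * 3, "F" * 3 + "Y" * 3 + "W" * 3 + "L" * 3]
    infos = [build_logo(list(pool)).info[0] for pool in pools]
    assert all(a >= b - 1e-12 for a, b in zip(infos, infos[1:]))


def test_logo_small_sample_correction():
    logo = build_logo(["F"] * 10, small_sample_correction=True)
    e_n = (19 / (2 * 10)) / math.log(2)
    assert logo.info[0] == pytest.approx(LOG2_20 - e_n)


def test_logo_gap_policies():
    seqs = ["F-", "F-", "Y-", "YF"]
    ignore = build_logo(seqs, gap_policy="ignore_gaps")
    assert ignore.freqs[0].sum() == pytest.approx(1.0)
    count = build_logo(seqs, gap_policy="count_gaps")
    assert count.freqs[1].sum() == pytest.approx(0.25)  # 1 F of 4 rows


def test_logo_unequal_lengths_raise():
    with pytest.raises(ValueError, match="alignment"):
        build_logo(["FF", "F"])


def test_pad_cterm_right_aligns():
    assert pad_cterm(["FGL", "YNFGL"]) == ["--FGL", "YNFGL"]
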