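"""Line-shape prediction and multi-variant strip matching."""

import numpy as np
import pytest

from decop import patterns
from decop.patterns import (
    MEAN_SHIFTS,
    Strip,
    generate_synthetic_strips,
    match_strips,
    predict_pattern,
    residue_model,
)
from decop.targets import builtin_spec

VARIANTS = {n: builtin_spec(n) for n in ("GOODCOP", "BADCOP1", "BADCOP2", "BADCOP3")}


def count_peaks_near(trace, axis, center_hz, window_hz=60.0, frac=0.3):
    sel = np.abs(axis - center_hz) <= window_hz
    seg = trace[sel]
    floor = frac * seg.max()
    return sum(
        1
        for i in range(1, seg.size - 1)
        if seg[i] >= floor and seg[i] > seg[i - 1] and seg[i] >= seg[i + 1]
    )


class TestPredictPattern:
    @pytest.mark.parametrize(
        "code,variant,expected",
        [
            ("A", "BADCOP1", "singlet"),   # Ala Cβ ≈ 19 inside [5,37]
            ("A", "BADCOP2", "doublet"),   # preserved below 26
            ("A", "GOODCOP", "doublet"),   # no Cβ decoupling at all
            ("G", "GOODCOP", "singlet"),   # no Cβ → no splitting
            ("G", "BADCOP3", "perturbed"), # Cα 45.4 below the 47 p.p.m. band
            ("S", "BADCOP3", "doublet"),   # Ser Cβ ≈ 64, outside [10,45]
            ("T", "BADCOP3", "doublet"),   # Thr Cβ ≈ 70
            ("L", "BADCOP3", "singlet"),   # Leu Cβ ≈ 42 inside [10,45]
            ("L", "BADCOP1", "doublet"),   # 42 outside [5,37]
        ],
    )
    def test_classification_table(self, code, variant, expected):
        assert predict_pattern(residue_model(code), VARIANTS[variant]) == expected

    def test_goodcop_splits_every_residue_except_glycine(self):
        for code in MEAN_SHIFTS:
            got = predict_pattern(residue_model(code), VARIANTS["GOODCOP"])
            assert got == ("singlet" if code == "G" else "doublet")

    def test_badcop3_only_ser_thr_split(self):
        for code in MEAN_SHIFTS:
            got = predict_pattern(residue_model(code), VARIANTS["BADCOP3"])
            if code == "G":
                assert got == "perturbed"
            elif code in ("S", "T"):
                assert got == "doublet"
            else:
                assert got == "singlet"

    def test_prediction_is_pure(self, badcop1_result):
        res = residue_model("A")
        spec = VARIANTS["BADCOP1"]
        first = predict_pattern(res, spec, pulse=badcop1_result.pulse)
        for _ in range(3):
            assert predict_pattern(res, spec, pulse=badcop1_result.pulse) == first

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            residue_model("Z")


class TestSyntheticStrips:
    def test_deterministic_given_seed(self):
        a = generate_synthetic_strips("GAVL", VARIANTS, noise_level=0.1, seed=42)
        b = generate_synthetic_strips("GAVL", VARIANTS, noise_level=0.1, seed=42)
        for sa, sb in zip(a.strips, b.strips):
            for name in a.variants:
                assert np.array_equal(sa.traces[name], sb.traces[name])

    def test_goodcop_traces_are_doublets_except_glycine(self):
        ss = generate_synthetic_strips("GAVLST", VARIANTS)
        for st in ss.strips:
            n = count_peaks_near(st.traces["GOODCOP"], ss.axis_hz, st.peak_hz)
            assert n == (1 if st.label.endswith("G") else 2)

    def test_badcop1_collapses_upfield_cbeta(self):
        ss = generate_synthetic_strips("AL", VARIANTS)
        # Ala Cβ 19 p.p.m. → singlet; Leu Cβ 42.3 → still a doublet
        assert count_peaks_near(ss.strip(0).traces["BADCOP1"], ss.axis_hz,
                                ss.strip(0).peak_hz) == 1
        assert count_peaks_near(ss.strip(1).traces["BADCOP1"], ss.axis_hz,
                                ss.strip(1).peak_hz) == 2


class TestMatchStrips:
    def test_identical_strips_correlate_perfectly(self):
        ss = generate_synthetic_strips("AA", VARIANTS)
        m = match_strips(ss.strip(0), [ss.strip(1)], ss.axis_hz)[0]
        assert m.retained
        for r in m.correlations.values():
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_cbeta_across_band_edge_excluded_despite_goodcop_match(self):
        # two spin systems with identical Cα; Cβ on opposite sides of the
        # BADCOP1 inversion edge → singlet vs doublet under BADCOP1 while
        # GOODCOP strips are identical
        r1 = patterns.ResidueModel("X1", 55.0, 30.0, 35.0)
        r2 = patterns.ResidueModel("X2", 55.0, 45.0, 35.0)
        ss = generate_synthetic_strips([r1, r2], VARIANTS)
        m_good = match_strips(ss.strip(0), [ss.strip(1)], ss.axis_hz,
                              variants=["GOODCOP"])[0]
        assert m_good.retained  # ambiguous on GOODCOP alone
        m_all = match_strips(ss.strip(0), [ss.strip(1)], ss.axis_hz)[0]
        assert not m_all.retained
        assert m_all.correlations["BADCOP1"] < 0.9

    def test_uncorrelated_noise_excluded(self, rng):
        n = 4096  # ~2 Hz/bin → ~60-point correlation windows
        axis = np.linspace(-4000, 4000, n)
        mk = lambda: Strip(
            label="n", peak_hz=0.0,
            traces={v: rng.standard_normal(n) for v in VARIANTS},
        )
        m = match_strips(mk(), [mk()], axis)[0]
        assert not m.retained
        assert all(abs(r) < 0.6 for r in m.correlations.values())

    def test_window_outside_axis_rejected(self):
        ss = generate_synthetic_strips("AA", VARIANTS)
        q = ss.strip(0)
        far = Strip(label="far", peak_hz=float(ss.axis_hz[-1]), traces=q.traces)
        with pytest.raises(ValueError):
            match_strips(q, [far], ss.axis_hz)

    def test_sequential_chain_recovered_without_false_exclusions(self):
        seq = "GGAVSTKLMDEF"
        ss = generate_synthetic_strips(seq, VARIANTS)
        for i in range(1, len(seq)):
            # the sequential trace in strip i is the predecessor's multiplet
            query = ss.strip(i - 1)
            matches = match_strips(query, ss.strips, ss.axis_hz)
            labels = {m.candidate: m for m in matches}
            true_match = labels[ss.strip(i - 1).label]
            assert true_match.retained
            assert true_match.min_correlation == pytest.approx(1.0, abs=1e-9)

    def test_adding_variants_never_adds_survivors(self):
        r1 = patterns.ResidueModel("X1", 55.0, 30.0, 35.0)
        r2 = patterns.ResidueModel("X2", 55.0, 45.0, 35.0)
        r3 = patterns.ResidueModel("X3", 55.0, 30.5, 35.0)
        ss = generate_synthetic_strips([r1, r2, r3], VARIANTS)
        names = ["GOODCOP", "BADCOP1", "BADCOP2", "BADCOP3"]
        survivors = []
        for k in range(1, len(names) + 1):
            ms = match_strips(ss.strip(0), ss.strips[1:], ss.axis_hz,
                              variants=names[:k])
            survivors.append(sum(m.retained for m in ms))
        assert all(a >= b for a, b in zip(survivors, survivors[1:]))
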