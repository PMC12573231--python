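import math
import random

import numpy as np
import pytest

from specannot.annotate import (
    FMR_OFFSETS,
    AnnotationSettings,
    UndefinedFMRError,
    annotation_statistics,
    error_graph,
    false_match_rate,
    match_fragments,
    sequence_coverage,
)
from specannot.fragmentation import TheoreticalFragment, generate_fragments, get_model
from specannot.chem import PROTON_MASS
from specannot.proforma import parse_proforma
from specannot.spectrum_io import Spectrum


def frag(mz_value, kind="b", position=1, charge=1, pep=0, label=None):
    neutral = mz_value * charge - charge * PROTON_MASS
    return TheoreticalFragment(
        kind=kind, peptidoform_index=pep, position=position, charge=charge,
        neutral_mass=neutral, label=label or f"{kind}{position}",
        variant=f"{kind}{position}@{mz_value}",
    )


def spectrum(mzs, intensities=None):
    mzs = np.asarray(mzs, dtype=float)
    if intensities is None:
        intensities = np.ones_like(mzs)
    return Spectrum(mz=mzs, intensity=np.asarray(intensities, dtype=float))


class TestMatching:
    def test_nearest_within_tolerance(self):
        s = spectrum([500.004, 500.011])
        r = match_fragments(s, [frag(500.000)], AnnotationSettings(tolerance=20))
        # 500.004 is 8 ppm away; 500.011 is 22 ppm, outside the window
        assert r.assignments == [0]

    def test_out_of_tolerance_unassigned(self):
        s = spectrum([500.011])
        r = match_fragments(s, [frag(500.000)], AnnotationSettings(tolerance=20))
        assert r.assignments == [None]

    def test_tie_breaks_to_lower_mz(self):
        s = spectrum([499.996, 500.004])
        r = match_fragments(s, [frag(500.000)],
                            AnnotationSettings(tolerance=0.01, tolerance_unit="th"))
        assert r.assignments == [0]

    def test_empty_spectrum(self):
        r = match_fragments(spectrum([]), [frag(500.0), frag(600.0)])
        assert r.assignments == [None, None]

    def test_many_fragments_one_peak(self):
        s = spectrum([500.000])
        r = match_fragments(s, [frag(500.000, "b", 1), frag(500.001, "y", 2)],
                            AnnotationSettings(tolerance=10))
        assert r.assignments == [0, 0]
        assert r.peak_annotations() == {0: [0, 1]}

    def test_matches_brute_force_oracle(self):
        """Nearest-in-tolerance assignment equals an O(n*m) scan."""
        rng = random.Random(3)
        settings = AnnotationSettings(tolerance=15)
        for _ in range(30):
            peaks = sorted(rng.uniform(100, 1500) for _ in range(rng.randint(0, 60)))
            frags = [frag(rng.uniform(100, 1500), position=i + 1)
                     for i in range(rng.randint(1, 40))]
            r = match_fragments(spectrum(peaks), frags, settings)
            for f, got in zip(frags, r.assignments):
                window = f.mz * 15e-6
                best, best_d = None, None
                for idx, p in enumerate(peaks):
                    d = abs(p - f.mz)
                    if d <= window and (best_d is None or d < best_d):
                        best, best_d = idx, d
                assert got == best


class TestCoverage:
    def _pep(self, registry, seq):
        return parse_proforma(seq, registry).peptidoforms[0]

    def test_rule_application(self, registry):
        pep = self._pep(registry, "ACDE")
        frags = [frag(200, "b", 1), frag(300, "b", 2), frag(150, "y", 1)]
        s = spectrum([200.0, 300.0, 150.0])
        r = match_fragments(s, frags, AnnotationSettings(tolerance=10))
        assert sequence_coverage(r, pep) == (3, 4)  # residues 1, 2, 4

    def test_no_matches(self, registry):
        pep = self._pep(registry, "ACDE")
        r = match_fragments(spectrum([]), [frag(200, "b", 1)])
        assert sequence_coverage(r, pep) == (0, 4)

    def test_a_series_covers_residue_one(self, registry):
        """a1..a(n-1) + y1 give full coverage (residue n from y1)."""
        pep = self._pep(registry, "ACDE")
        frags = [frag(100 * i, "a", i) for i in range(1, 4)] + [frag(450, "y", 1)]
        mzs = [f.mz for f in frags]
        r = match_fragments(spectrum(mzs), frags, AnnotationSettings(tolerance=10))
        assert sequence_coverage(r, pep) == (4, 4)

    def test_satellites_follow_parent_series_rule(self, registry):
        pep = self._pep(registry, "IVLT")
        frags = [frag(200, "d", 1), frag(300, "w", 1)]
        r = match_fragments(spectrum([200.0, 300.0]), frags,
                            AnnotationSettings(tolerance=10))
        assert sequence_coverage(r, pep) == (2, 4)  # d1 -> residue 1, w1 -> residue 4


class TestStatistics:
    def test_all_annotated(self):
        frags = [frag(200, "b", 1), frag(300, "b", 2)]
        r = match_fragments(spectrum([200.0, 300.0]), frags,
                            AnnotationSettings(tolerance=10))
        combined, _ = annotation_statistics(r)
        assert combined.fragments_found == 1.0
        assert combined.peaks_annotated == 1.0
        assert combined.intensity_annotated == 1.0

    def test_half_intensity(self):
        frags = [frag(200, "b", 1)]
        r = match_fragments(spectrum([200.0, 900.0], [5.0, 5.0]), frags,
                            AnnotationSettings(tolerance=10))
        combined, _ = annotation_statistics(r)
        assert combined.intensity_annotated == pytest.approx(0.5)
        assert combined.peaks_annotated == pytest.approx(0.5)

    def test_chimeric_members_and_combined(self, registry):
        cp = parse_proforma("AAA+GGG", registry)
        frags = [frag(200, "b", 1, pep=0), frag(300, "b", 1, pep=1)]
        r = match_fragments(spectrum([200.0, 300.0]), frags,
                            AnnotationSettings(tolerance=10))
        combined, members = annotation_statistics(r, cp)
        assert len(members) == 2
        assert combined.peaks_annotated == 1.0
        assert members[0].peaks_annotated == pytest.approx(0.5)

    def test_monotone_in_tolerance(self, registry, ethcd_model):
        cp = parse_proforma("PEPTIDEK/2", registry)
        frags = generate_fragments(cp, ethcd_model, 2)
        rng = np.random.default_rng(11)
        mzs = np.sort(rng.uniform(100, 900, size=300))
        s = spectrum(mzs)
        prev_peaks = prev_frags = -1.0
        for tol in (1.0, 5.0, 20.0, 100.0, 500.0):
            r = match_fragments(s, frags, AnnotationSettings(tolerance=tol))
            combined, _ = annotation_statistics(r)
            assert combined.peaks_annotated >= prev_peaks
            assert combined.fragments_found >= prev_frags
            prev_peaks, prev_frags = combined.peaks_annotated, combined.fragments_found


class TestFalseMatchRate:
    def test_offsets_are_fifty_around_pi(self):
        assert len(FMR_OFFSETS) == 50
        assert min(FMR_OFFSETS) == pytest.approx(math.pi - 25)
        assert max(FMR_OFFSETS) == pytest.approx(math.pi + 24)

    def test_sparse_spectrum_low_fmr(self, registry, bare_model):
        cp = parse_proforma("PEPTIDEK", registry)
        frags = [f for f in generate_fragments(cp, bare_model, 1)]
        s = spectrum([f.mz for f in frags])
        fmr_p, fmr_i = false_match_rate(s, frags, AnnotationSettings(tolerance=10))
        assert 0.0 <= fmr_p < 0.05
        assert 0.0 <= fmr_i < 0.05

    def test_dense_grid_fmr_near_one(self):
        frags = [frag(300.0 + 17 * i, position=i + 1) for i in range(10)]
        grid = np.arange(250.0, 550.0, 0.05)
        s = spectrum(grid)
        fmr_p, fmr_i = false_match_rate(
            s, frags, AnnotationSettings(tolerance=0.03, tolerance_unit="th"))
        assert fmr_p == pytest.approx(1.0, abs=0.05)
        assert fmr_i == pytest.approx(1.0, abs=0.05)

    def test_undefined_when_nothing_matches(self):
        s = spectrum([1000.0])
        with pytest.raises(UndefinedFMRError):
            false_match_rate(s, [frag(200.0)], AnnotationSettings(tolerance=5))


class TestErrorGraph:
    def test_all_annotated_gives_empty(self):
        frags = [frag(200, "c", 1)]
        r = match_fragments(spectrum([200.0]), frags, AnnotationSettings(tolerance=10))
        assert error_graph(r, ["c"]) == []

    def test_signed_distance(self):
        frags = [frag(500.0, "c", 1)]
        r = match_fragments(spectrum([500.5]), frags, AnnotationSettings(tolerance=10))
        ((peak_mz, dist),) = error_graph(r, ["c"])
        assert peak_mz == pytest.approx(500.5)
        assert dist == pytest.approx(0.5)

    def test_constant_offset_signature(self):
        frags = [frag(300.0 + 50 * i, "c", i + 1) for i in range(5)]
        shifted_peaks = [f.mz + 0.25 for f in frags]
        r = match_fragments(spectrum(shifted_peaks), frags,
                            AnnotationSettings(tolerance=10))
        graph = error_graph(r, ["c"])
        assert len(graph) == 5
        assert all(d == pytest.approx(0.25, abs=1e-9) for _, d in graph)

    def test_requires_selection(self):
        r = match_fragments(spectrum([100.0]), [frag(500.0)])
        with pytest.raises(ValueError):
            error_graph(r, [])
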