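"""Fragment-to-peak matching, annotation statistics, and the false match rate.

Matching follows the nearest-peak rule: each theoretical fragment is
assigned to the measured peak closest in m/z within the tolerance (ppm or
Th).  Several fragments may share one peak — no disambiguation is applied,
all valid annotations are reported.  Ties between equidistant peaks break
toward the lower m/z.

Four statistics summarize an annotation: the fraction of distinct
theoretical fragments found, the fraction of peaks annotated, the fraction
of total intensity annotated, and the backbone sequence coverage.

The false match rate shifts the spectrum by pi + k Th for k = -25..24 (50
offsets; the irrational pi term avoids accidental re-matching of isotope
patterns on integer shifts), re-matches each shifted spectrum against the
same fragment list, and reports the mean matched-peak count and matched
intensity relative to the unshifted annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fragmentation import TheoreticalFragment
from .proforma import CompoundPeptidoform, Peptidoform
from .spectrum_io import Spectrum, noise_filter

__all__ = [
    "AnnotationSettings",
    "AnnotationStatistics",
    "AnnotationResult",
    "UndefinedFMRError",
    "match_fragments",
    "sequence_coverage",
    "annotation_statistics",
    "false_match_rate",
    "error_graph",
    "FMR_OFFSETS",
]

#: The 50 spectrum shifts used for the false-match-rate estimate (Th).
FMR_OFFSETS: Tuple[float, ...] = tuple(math.pi + k for k in range(-25, 25))


class UndefinedFMRError(ValueError):
    """FMR is undefined when the unshifted annotation matches nothing."""


@dataclass(frozen=True)
class AnnotationSettings:
    """Matching settings: tolerance, noise filter, match mode."""

    tolerance: float = 20.0
    tolerance_unit: str = "ppm"  # "ppm" | "th"
    noise_mode: str = "absolute"
    noise_value: float = 1.0
    match_mode: str = "monoisotopic"
    decharged_precursors: bool = False

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.tolerance_unit.lower() not in ("ppm", "th"):
            raise ValueError(f"unknown tolerance unit {self.tolerance_unit!r}")

    def window(self, mz: float) -> float:
        """Half-width of the matching window at ``mz``, in Th."""
        if self.tolerance_unit.lower() == "ppm":
            return mz * self.tolerance * 1e-6
        return self.tolerance

    def to_dict(self) -> dict:
        return {
            "tolerance": self.tolerance,
            "tolerance_unit": self.tolerance_unit,
            "noise_mode": self.noise_mode,
            "noise_value": self.noise_value,
            "match_mode": self.match_mode,
        }


@dataclass(frozen=True)
class AnnotationStatistics:
    """The four headline statistics of one annotation."""

    fragments_found: float
    peaks_annotated: float
    intensity_annotated: float
    coverage: Tuple[int, int]  # (covered residues, length); (0, 0) for pooled stats

    def to_dict(self) -> dict:
        return {
            "fragments_found": self.fragments_found,
            "peaks_annotated": self.peaks_annotated,
            "intensity_annotated": self.intensity_annotated,
            "sequence_coverage": list(self.coverage),
        }


@dataclass
class AnnotationResult:
    """Peak/fragment assignments for one (filtered) spectrum."""

    spectrum: Spectrum
    fragments: List[TheoreticalFragment]
    #: per fragment: index of the assigned peak, or None
    assignments: List[Optional[int]]
    settings: AnnotationSettings

    @property
    def matched_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.spectrum), dtype=bool)
        for peak in self.assignments:
            if peak is not None:
                mask[peak] = True
        return mask

    def peak_annotations(self) -> Dict[int, List[int]]:
        """peak index -> list of fragment indices assigned to it."""
        out: Dict[int, List[int]] = {}
        for f_idx, peak in enumerate(self.assignments):
            if peak is not None:
                out.setdefault(peak, []).append(f_idx)
        return out

    def matched_fragments(self) -> List[TheoreticalFragment]:
        return [f for f, p in zip(self.fragments, self.assignments) if p is not None]

    def n_matched_peaks(self) -> int:
        return int(self.matched_mask.sum())

    def matched_intensity(self) -> float:
        return float(self.spectrum.intensity[self.matched_mask].sum())


def _nearest_in_tolerance(
    peaks_mz: np.ndarray, target: float, window: float
) -> Optional[int]:
    """Index of the nearest peak within +-window of target; ties -> lower m/z."""
    if len(peaks_mz) == 0:
        return None
    pos = int(np.searchsorted(peaks_mz, target))
    best: Optional[int] = None
    best_dist = window
    for cand in (pos - 1, pos):
        if 0 <= cand < len(peaks_mz):
            dist = abs(peaks_mz[cand] - target)
            # strict '<' after scanning low-to-high breaks ties toward lower m/z
            if dist <= window and (best is None or dist < best_dist):
                best = cand
                best_dist = dist
    return best


def match_fragments(
    spectrum: Spectrum,
    fragments: Sequence[TheoreticalFragment],
    settings: AnnotationSettings = AnnotationSettings(),
) -> AnnotationResult:
    """Assign each theoretical fragment its nearest in-tolerance peak.

    The spectrum is expected to be noise-filtered already; every fragment
    maps to at most one peak, while one peak may collect several fragments.
    """
    peaks = spectrum.mz
    assignments: List[Optional[int]] = []
    for frag in fragments:
        target = frag.mz
        assignments.append(_nearest_in_tolerance(peaks, target, settings.window(target)))
    return AnnotationResult(spectrum, list(fragments), assignments, settings)


def sequence_coverage(result: AnnotationResult, peptidoform: Peptidoform,
                      peptidoform_index: int = 0) -> Tuple[int, int]:
    """(covered residues, length) from matched backbone/satellite fragments.

    Residue i is covered iff a matched N-terminal-series fragment has
    position i or a matched C-terminal-series fragment has position
    n - i + 1 (satellites follow their parent series' index rule).
    """
    n = len(peptidoform)
    covered = set()
    for frag in result.matched_fragments():
        if frag.peptidoform_index != peptidoform_index:
            continue
        residue = frag.covered_residue(n)
        if residue is not None and 1 <= residue <= n:
            covered.add(residue)
    return len(covered), n


def annotation_statistics(
    result: AnnotationResult,
    cp: Optional[CompoundPeptidoform] = None,
) -> Tuple[AnnotationStatistics, List[AnnotationStatistics]]:
    """Combined statistics plus one entry per chimeric member.

    Denominators come from the noise-filtered spectrum presented to
    matching; fragments are counted as distinct (kind, position, variant,
    loss, charge) tuples.  Pooled coverage is reported as (0, 0) — coverage
    is only meaningful per member.
    """
    n_peaks = len(result.spectrum)
    total_intensity = result.spectrum.total_intensity

    def stats_for(member: Optional[int]) -> AnnotationStatistics:
        frag_ids = set()
        matched_ids = set()
        peak_mask = np.zeros(n_peaks, dtype=bool)
        for frag, peak in zip(result.fragments, result.assignments):
            if member is not None and frag.peptidoform_index != member:
                continue
            frag_ids.add(frag.identity())
            if peak is not None:
                matched_ids.add(frag.identity())
                peak_mask[peak] = True
        coverage = (0, 0)
        if member is not None and cp is not None:
            coverage = sequence_coverage(result, cp.peptidoforms[member], member)
        return AnnotationStatistics(
            fragments_found=len(matched_ids) / len(frag_ids) if frag_ids else 0.0,
            peaks_annotated=float(peak_mask.sum()) / n_peaks if n_peaks else 0.0,
            intensity_annotated=(
                float(result.spectrum.intensity[peak_mask].sum()) / total_intensity
                if total_intensity > 0 else 0.0
            ),
            coverage=coverage,
        )

    combined = stats_for(None)
    members = []
    if cp is not None:
        members = [stats_for(i) for i in range(len(cp.peptidoforms))]
    return combined, members


def false_match_rate(
    spectrum: Spectrum,
    fragments: Sequence[TheoreticalFragment],
    settings: AnnotationSettings = AnnotationSettings(),
    unshifted: Optional[AnnotationResult] = None,
) -> Tuple[float, float]:
    """(FMR by matched peaks, FMR by matched intensity).

    Re-matches the spectrum shifted by pi + k Th (k = -25..24) and divides
    the mean matched-peak count / matched intensity over the 50 offsets by
    the unshifted values.  Raises :class:`UndefinedFMRError` when the
    unshifted annotation matches nothing.
    """
    if unshifted is None:
        unshifted = match_fragments(spectrum, fragments, settings)
    true_peaks = unshifted.n_matched_peaks()
    true_intensity = unshifted.matched_intensity()
    if true_peaks == 0:
        raise UndefinedFMRError("no annotated peaks at 0 Th offset; FMR is undefined")
    peak_counts = []
    intensities = []
    for offset in FMR_OFFSETS:
        shifted = match_fragments(spectrum.shifted(offset), fragments, settings)
        peak_counts.append(shifted.n_matched_peaks())
        intensities.append(shifted.matched_intensity())
    fmr_peaks = float(np.mean(peak_counts)) / true_peaks
    fmr_intensity = (float(np.mean(intensities)) / true_intensity
                     if true_intensity > 0 else 0.0)
    return fmr_peaks, fmr_intensity


def error_graph(
    result: AnnotationResult,
    series_selection: Sequence[str],
) -> List[Tuple[float, float]]:
    """(peak m/z, signed distance to nearest selected theoretical fragment)
    for every unannotated peak; distance is peak minus theoretical, in Th.

    The constant-offset signature of a locally wrong sequence shows up as a
    run of entries at the same distance.
    """
    if not series_selection:
        raise ValueError("series selection must be non-empty")
    selected = sorted(f.mz for f in result.fragments if f.kind in set(series_selection))
    if not selected:
        return []
    theo = np.asarray(selected)
    out: List[Tuple[float, float]] = []
    matched = result.matched_mask
    for peak_idx in range(len(result.spectrum)):
        if matched[peak_idx]:
            continue
        peak_mz = float(result.spectrum.mz[peak_idx])
        pos = int(np.searchsorted(theo, peak_mz))
        best = None
        for cand in (pos - 1, pos):
            if 0 <= cand < len(theo):
                d = peak_mz - float(theo[cand])
                if best is None or abs(d) < abs(best):
                    best = d
        out.append((peak_mz, best))
    return out
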