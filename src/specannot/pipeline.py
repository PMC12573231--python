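"""High-level workflows: synthetic spectra, single-spectrum annotation
reports, and batch (multi-PSM) annotation.

The synthetic-spectrum generator builds a centroided MS2 spectrum directly
from a peptidoform's theoretical fragments: a chosen fraction of the
distinct fragment m/z values is realized as peaks with log-uniform
intensities, optional Gaussian m/z jitter (in ppm), and optional uniform
random noise peaks.  All randomness flows through one seeded generator, so
fixed parameters reproduce byte-identical spectra.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotate import (
    AnnotationResult,
    AnnotationSettings,
    AnnotationStatistics,
    UndefinedFMRError,
    annotation_statistics,
    false_match_rate,
    match_fragments,
    sequence_coverage,
)
from .fragmentation import (
    FragmentationModel,
    TheoreticalFragment,
    generate_fragments,
)
from .modifications import ModificationRegistry, load_modification_registry
from .proforma import CompoundPeptidoform, parse_proforma
from .spectrum_io import Spectrum, get_spectrum, noise_filter, read_mgf, read_mzml

__all__ = [
    "SynthesisParams",
    "synthesize_spectrum",
    "AnnotationReport",
    "annotate_spectrum",
    "multiannotate",
    "fragment_table",
]


@dataclass(frozen=True)
class SynthesisParams:
    """Parameters of the synthetic-spectrum generator."""

    seed: int
    precursor_charge: int = 2
    fraction: float = 1.0  # fraction of distinct theoretical m/z realized
    intensity_range: Tuple[float, float] = (1e3, 1e5)  # log-uniform
    jitter_ppm: float = 0.0
    noise_peaks: int = 0
    noise_mz_range: Tuple[float, float] = (100.0, 1500.0)

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if self.jitter_ppm < 0:
            raise ValueError("jitter sigma must be >= 0")


def synthesize_spectrum(
    cp: CompoundPeptidoform,
    model: FragmentationModel,
    params: SynthesisParams,
) -> Tuple[Spectrum, List[Tuple[TheoreticalFragment, int]]]:
    """Build a spectrum from a peptidoform's theoretical fragments.

    Returns the spectrum and the ground truth: every realized fragment with
    the index of its peak in the (sorted) spectrum.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    fragments = generate_fragments(cp, model, params.precursor_charge)
    # distinct m/z positions (several fragments may share one)
    mz_to_frags: Dict[float, List[TheoreticalFragment]] = {}
    for f in fragments:
        mz_to_frags.setdefault(round(f.mz, 6), []).append(f)
    positions = sorted(mz_to_frags)
    n_realized = int(round(params.fraction * len(positions)))
    realized_idx = sorted(rng.choice(len(positions), size=n_realized, replace=False))
    lo, hi = params.intensity_range
    mzs: List[float] = []
    intensities: List[float] = []
    realized_positions: List[float] = []
    for i in realized_idx:
        mz_v = positions[i]
        if params.jitter_ppm > 0:
            mz_v += rng.normal(0.0, params.jitter_ppm * mz_v * 1e-6)
        mzs.append(mz_v)
        intensities.append(float(np.exp(rng.uniform(math.log(lo), math.log(hi)))))
        realized_positions.append(positions[i])
    for _ in range(params.noise_peaks):
        mzs.append(float(rng.uniform(*params.noise_mz_range)))
        intensities.append(float(np.exp(rng.uniform(math.log(lo), math.log(hi)))))
    precursor = max((f.mz for f in fragments if f.kind == "precursor"), default=None)
    spectrum = Spectrum(
        mz=np.array(mzs), intensity=np.array(intensities),
        identifier=f"synthetic:{cp.proforma_text()}",
        precursor_mz=precursor, precursor_charge=params.precursor_charge,
    )
    # map realized fragments to their (sorted) peak indices
    order = {round(m, 6): int(np.argmin(np.abs(spectrum.mz - m))) for m in realized_positions}
    ground_truth = [
        (f, order[pos])
        for pos in (round(p, 6) for p in realized_positions)
        for f in mz_to_frags[pos]
    ]
    return spectrum, ground_truth


@dataclass
class AnnotationReport:
    """Everything one annotation run produced, JSON/TSV-serializable."""

    proforma: str
    model_name: str
    settings: AnnotationSettings
    result: AnnotationResult
    combined: AnnotationStatistics
    members: List[AnnotationStatistics]
    fmr_peaks: Optional[float]
    fmr_intensity: Optional[float]

    def to_dict(self) -> dict:
        peak_ann = {
            str(p): [self.result.fragments[i].label for i in idxs]
            for p, idxs in self.result.peak_annotations().items()
        }
        return {
            "proforma": self.proforma,
            "model": self.model_name,
            "settings": self.settings.to_dict(),
            "statistics": {
                "combined": self.combined.to_dict(),
                "members": [m.to_dict() for m in self.members],
            },
            "false_match_rate": {
                "peaks": self.fmr_peaks,
                "intensity": self.fmr_intensity,
            },
            "n_peaks": len(self.result.spectrum),
            "n_fragments": len(self.result.fragments),
            "n_matched_peaks": self.result.n_matched_peaks(),
            "peak_annotations": peak_ann,
        }

    def annotation_table(self) -> pd.DataFrame:
        """Per-peak table: m/z, intensity, semicolon-joined fragment labels."""
        ann = self.result.peak_annotations()
        rows = []
        for i in range(len(self.result.spectrum)):
            labels = ";".join(self.result.fragments[j].label for j in ann.get(i, ()))
            rows.append({
                "mz": float(self.result.spectrum.mz[i]),
                "intensity": float(self.result.spectrum.intensity[i]),
                "annotations": labels,
            })
        return pd.DataFrame(rows, columns=["mz", "intensity", "annotations"])


def annotate_spectrum(
    spectrum: Spectrum,
    cp: CompoundPeptidoform,
    model: FragmentationModel,
    settings: AnnotationSettings = AnnotationSettings(),
    compute_fmr: bool = True,
) -> AnnotationReport:
    """Noise-filter, generate, match, and summarize one spectrum."""
    filtered = noise_filter(spectrum, settings.noise_mode, settings.noise_value)
    charge = cp.precursor_charge or spectrum.precursor_charge
    fragments = generate_fragments(cp, model, charge)
    result = match_fragments(filtered, fragments, settings)
    combined, members = annotation_statistics(result, cp)
    fmr_p = fmr_i = None
    if compute_fmr:
        try:
            fmr_p, fmr_i = false_match_rate(filtered, fragments, settings, unshifted=result)
        except UndefinedFMRError:
            pass
    return AnnotationReport(
        proforma=cp.proforma_text(),
        model_name=model.name,
        settings=settings,
        result=result,
        combined=combined,
        members=members,
        fmr_peaks=fmr_p,
        fmr_intensity=fmr_i,
    )


def coverage_by_series(
    result: AnnotationResult, cp: CompoundPeptidoform, member: int = 0
) -> Dict[str, float]:
    """Per-ion-series coverage fractions for one member."""
    n = len(cp.peptidoforms[member])
    per_series: Dict[str, set] = {}
    for frag in result.matched_fragments():
        if frag.peptidoform_index != member:
            continue
        residue = frag.covered_residue(n)
        if residue is not None:
            per_series.setdefault(frag.kind, set()).add(residue)
    return {kind: len(res) / n for kind, res in sorted(per_series.items())}


def multiannotate(
    psms: Union[str, Path, pd.DataFrame],
    model: FragmentationModel,
    settings: AnnotationSettings = AnnotationSettings(),
    registry: Optional[ModificationRegistry] = None,
    compute_fmr: bool = True,
) -> Tuple[pd.DataFrame, int]:
    """Annotate a batch of PSMs.

    ``psms`` is a TSV (or DataFrame) with columns ``file``,
    ``scan_or_index``, ``proforma`` and optional ``charge``.  Rows that
    fail to resolve are skipped and counted; the returned frame has one row
    per successful PSM with the four statistics, per-series coverage, and
    the FMR pair.
    """
    if registry is None:
        registry = load_modification_registry()
    if not isinstance(psms, pd.DataFrame):
        psms = pd.read_csv(psms, sep="\t")
    required = {"file", "scan_or_index", "proforma"}
    missing = required - set(psms.columns)
    if missing:
        raise ValueError(f"PSM table is missing columns {sorted(missing)}")
    if len(psms) == 0:
        raise ValueError("PSM table is empty")

    cache: Dict[str, List[Spectrum]] = {}
    rows: List[dict] = []
    skipped = 0
    for _, row in psms.iterrows():
        try:
            path = str(row["file"])
            if path not in cache:
                cache[path] = (read_mzml(path) if path.lower().endswith(".mzml")
                               else read_mgf(path))
            sel = int(row["scan_or_index"])
            try:
                spectrum = get_spectrum(cache[path], scan=sel)
            except KeyError:
                spectrum = get_spectrum(cache[path], index=sel)
            cp = parse_proforma(str(row["proforma"]), registry)
            if "charge" in psms.columns and not pd.isna(row.get("charge")):
                for pep in cp.peptidoforms:
                    if pep.charge is None:
                        pep.charge = int(row["charge"])
            report = annotate_spectrum(spectrum, cp, model, settings, compute_fmr)
            series_cov = coverage_by_series(report.result, cp, member=0)
            cov, length = report.members[0].coverage
            out = {
                "file": path,
                "scan_or_index": sel,
                "proforma": str(row["proforma"]),
                "fragments_found": report.combined.fragments_found,
                "peaks_annotated": report.combined.peaks_annotated,
                "intensity_annotated": report.combined.intensity_annotated,
                "coverage": cov,
                "length": length,
                "fmr_peaks": report.fmr_peaks,
                "fmr_intensity": report.fmr_intensity,
            }
            for kind, frac in series_cov.items():
                out[f"coverage_{kind}"] = frac
            rows.append(out)
        except Exception:
            skipped += 1
    if not rows:
        raise ValueError("every PSM row failed to resolve")
    return pd.DataFrame(rows), skipped


def fragment_table(
    cp: CompoundPeptidoform,
    model: FragmentationModel,
    precursor_charge: Optional[int] = None,
) -> pd.DataFrame:
    """All theoretical fragments as a table (label, kind, neutral mass, m/z)."""
    frags = generate_fragments(cp, model, precursor_charge)
    return pd.DataFrame([
        {
            "label": f.label,
            "kind": f.kind,
            "peptidoform": f.peptidoform_index + 1,
            "position": f.position,
            "charge": f.charge,
            "neutral_mass": f.neutral_mass,
            "mz": f.mz,
            "losses": ",".join(f.losses),
            "variant": f.variant,
        }
        for f in frags
    ])
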