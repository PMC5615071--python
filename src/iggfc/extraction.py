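"""Targeted glycopeptide quantification from centroided MS1 runs.

For every panel analyte the signal of the first three isotopologues in 2+
and 3+ charge state is summed over scans within +/-10 s of the expected
retention time and +/-0.04 Th of the target m/z (both windows closed),
background-corrected and summed into one intensity per analyte.  Before
extraction the run is recalibrated with a single global m/z offset estimated
from the four most abundant glycopeptides (G0F, G1F, G2F, G2FS1) in both
charge states, and retention times are aligned to a reference run by a
single global shift of the calibrant's chromatographic apex.

The background under each target window is estimated from two flanking m/z
windows ([-0.12, -0.04) and (0.04, 0.12] Th) over the same RT window: the
median flank-peak intensity times the expected number of flank-density peaks
in the signal window.  The estimator is homogeneous of degree one in the
intensities, so extraction is linear under global intensity scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mzml_io import RunSpectra
from .panel import Analyte, Panel

MZ_WINDOW = 0.04       # Th, closed on both sides
RT_WINDOW = 10.0       # s, closed on both sides
FLANK_OUTER = 0.12     # Th, outer edge of the background flanks
CHARGES = (2, 3)
N_ISOTOPES = 3
S2B_THRESHOLD = 3.0
CALIBRANT_GLYCOFORMS = ("G0F", "G1F", "G2F", "G2FS1")


@dataclass
class AnalyteSignal:
    analyte: Analyte
    raw_intensity: float      # background-corrected, clamped at 0
    background_level: float
    s2b: float
    passes_s2b: bool
    rt_in_range: bool = True


class _FlatRun:
    """Run flattened to parallel (rt, mz, intensity) peak arrays, RT-sorted."""

    def __init__(self, run: RunSpectra):
        self.run = run
        if run.scans:
            self.rt = np.concatenate(
                [np.full(s.mz.size, s.rt) for s in run.scans])
            self.mz = np.concatenate([s.mz for s in run.scans])
            self.intensity = np.concatenate([s.intensity for s in run.scans])
        else:
            self.rt = self.mz = self.intensity = np.empty(0)
        self.rt_min = run.scans[0].rt if run.scans else np.inf
        self.rt_max = run.scans[-1].rt if run.scans else -np.inf

    def rt_slice(self, lo: float, hi: float):
        """(mz, intensity) of peaks with rt in [lo, hi]; rt array is sorted."""
        i = np.searchsorted(self.rt, lo, side="left")
        j = np.searchsorted(self.rt, hi, side="right")
        return self.mz[i:j], self.intensity[i:j]


def recalibrate(run: RunSpectra, panel: Panel, coarse_window: float = 0.2,
                rt_window: float = RT_WINDOW) -> tuple[RunSpectra, float]:
    """Estimate and remove a single global m/z offset.

    The most intense peak within ``coarse_window`` of each calibrant target
    (monoisotopic m/z of G0F/G1F/G2F/G2FS1 per subclass, 2+ and 3+) in each
    in-window scan contributes one observed-minus-theoretical difference;
    the offset is their median.  Fewer than two matches gives offset 0 with
    a warning.
    """
    diffs = []
    flat = _FlatRun(run)
    for analyte in panel.analytes:
        if analyte.shorthand not in CALIBRANT_GLYCOFORMS:
            continue
        rt_mask = np.abs(flat.rt - analyte.expected_rt) <= rt_window
        for z in CHARGES:
            theo = analyte.target_mz(z)[0]
            m = rt_mask & (np.abs(flat.mz - theo) <= coarse_window)
            if not m.any():
                continue
            # per-scan most intense match
            sub = pd.DataFrame({"rt": flat.rt[m], "mz": flat.mz[m],
                                "i": flat.intensity[m]})
            best = sub.loc[sub.groupby("rt")["i"].idxmax()]
            diffs.extend((best["mz"] - theo).tolist())
    if len(diffs) < 2:
        warnings.warn("too few calibrant peaks found; m/z offset left at 0")
        return run, 0.0
    offset = float(np.median(diffs))
    return run.with_mz_offset(-offset), offset


def _calibrant_apex(run: RunSpectra, calibrant: Analyte,
                    coarse_rt: float = 60.0) -> float | None:
    """RT of the scan with the highest summed calibrant-window intensity."""
    best_rt, best_int = None, 0.0
    for scan in run.scans:
        if abs(scan.rt - calibrant.expected_rt) > coarse_rt:
            continue
        total = 0.0
        for z in CHARGES:
            for mz in calibrant.target_mz(z):
                m = np.abs(scan.mz - mz) <= MZ_WINDOW
                total += float(scan.intensity[m].sum())
        if total > best_int:
            best_rt, best_int = scan.rt, total
    return best_rt


def align_rt(runs: list, calibrant: Analyte,
             reference: RunSpectra | None = None) -> list:
    """Align runs to a reference by the calibrant chromatographic apex.

    Returns [(shifted_run, shift), ...] with ``shift`` added to scan RTs so
    the calibrant apex matches the reference apex.  A missing apex leaves
    the run unshifted with a warning.
    """
    reference = reference if reference is not None else runs[0]
    ref_apex = _calibrant_apex(reference, calibrant)
    out = []
    for run in runs:
        apex = _calibrant_apex(run, calibrant)
        if ref_apex is None or apex is None:
            warnings.warn(f"calibrant apex not found for {run.sample_id or 'run'}; "
                          "RT shift left at 0")
            out.append((run, 0.0))
            continue
        shift = ref_apex - apex
        out.append((run.shifted(shift), shift))
    return out


def extract_analyte(run: RunSpectra, analyte: Analyte,
                    _flat: _FlatRun | None = None) -> AnalyteSignal:
    """Windowed isotope summation with flanking-window background correction."""
    flat = _flat if _flat is not None else _FlatRun(run)
    if not (flat.rt_min <= analyte.expected_rt <= flat.rt_max):
        warnings.warn(f"expected RT of {analyte.subclass}-{analyte.shorthand} "
                      "outside run RT range")
        return AnalyteSignal(analyte, 0.0, 0.0, 0.0, False, rt_in_range=False)
    rt_mz, rt_int = flat.rt_slice(analyte.expected_rt - RT_WINDOW,
                                  analyte.expected_rt + RT_WINDOW)

    total_raw = 0.0
    total_bg = 0.0
    for z in CHARGES:
        for target in analyte.target_mz(z, N_ISOTOPES):
            d = rt_mz - target
            sig = rt_int[np.abs(d) <= MZ_WINDOW].sum()
            fl = (np.abs(d) > MZ_WINDOW) & (np.abs(d) <= FLANK_OUTER)
            n_flank = int(fl.sum())
            if n_flank:
                width_ratio = (2 * MZ_WINDOW) / (2 * (FLANK_OUTER - MZ_WINDOW))
                bg = float(np.median(rt_int[fl])) * n_flank * width_ratio
            else:
                bg = 0.0
            total_raw += max(float(sig) - bg, 0.0)
            total_bg += bg
    if total_bg > 0:
        s2b = total_raw / total_bg
    else:
        s2b = np.inf if total_raw > 0 else 0.0
    return AnalyteSignal(analyte, total_raw, total_bg, s2b,
                         bool(s2b > S2B_THRESHOLD))


def extract_run(run: RunSpectra, panel: Panel) -> pd.DataFrame:
    """Extract every panel analyte from one run.

    Returns a tidy frame: subclass, shorthand, raw_intensity, background,
    s2b, passes_s2b.
    """
    flat = _FlatRun(run)
    rows = []
    for analyte in panel.analytes:
        sig = extract_analyte(run, analyte, _flat=flat)
        rows.append({"subclass": analyte.subclass,
                     "shorthand": analyte.shorthand,
                     "raw_intensity": sig.raw_intensity,
                     "background": sig.background_level,
                     "s2b": sig.s2b,
                     "passes_s2b": sig.passes_s2b})
    return pd.DataFrame(rows)


def write_extraction_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_extraction_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
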