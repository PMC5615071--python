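"""Curation of raw analyte intensities into analysis-ready trait tables.

Pipeline order (fixed): exclude flagged analytes -> normalize to percentages
per subclass -> apply the signal-quality threshold -> derive glycosylation
features -> ComBat batch correction with plates as batches -> 5-SD
winsorization -> natural-log transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combat import combat_adjust
from .traits import TRAIT_NAMES, PER_GLYCAN_NAMES, compute_traits

DEFAULT_QUALITY_THRESHOLD = 50.0  # % of intensity from analytes with S/B > 3


@dataclass
class CurationConfig:
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
    combat_on: str = "traits"     # "traits" or "glycoforms"
    log_policy: str = "offset"    # strict | offset | drop
    log_offset: float | None = None  # None: half the smallest positive value
    winsorize_sds: float = 5.0
    excluded_analytes: list = field(default_factory=list)  # (subclass, shorthand)


def exclude_analytes(signals: pd.DataFrame, exclusions) -> pd.DataFrame:
    """Drop flagged (subclass, shorthand) analytes before normalization."""
    if not exclusions:
        return signals
    known = set(zip(signals["subclass"], signals["shorthand"]))
    for pair in exclusions:
        if tuple(pair) not in known:
            raise KeyError(f"unknown analyte in exclusion list: {pair}")
    mask = [
        (s, g) not in {tuple(p) for p in exclusions}
        for s, g in zip(signals["subclass"], signals["shorthand"])
    ]
    out = signals.loc[mask].reset_index(drop=True)
    if out.empty:
        raise ValueError("all analytes excluded; nothing left to normalize")
    return out


def normalize(signals: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw intensities to percentages summing to 100 per subclass.

    Input: one sample's extraction frame (subclass, shorthand,
    raw_intensity, passes_s2b).  Output adds ``pct``; subclasses whose total
    intensity is zero get ``included=False`` and NaN percentages.
    """
    out = signals.copy()
    out["pct"] = np.nan
    out["included"] = True
    for subclass, idx in out.groupby("subclass").groups.items():
        total = out.loc[idx, "raw_intensity"].sum()
        if total <= 0:
            out.loc[idx, "included"] = False
            continue
        if out.loc[idx].empty:
            raise ValueError(f"no analytes to normalize for {subclass}")
        out.loc[idx, "pct"] = 100.0 * out.loc[idx, "raw_intensity"] / total
    return out


def quality_fraction(signals: pd.DataFrame) -> pd.Series:
    """% of each subclass's intensity from analytes with S/B > 3."""
    def _qf(g):
        total = g["raw_intensity"].sum()
        if total <= 0:
            return 0.0
        return 100.0 * g.loc[g["passes_s2b"], "raw_intensity"].sum() / total
    return signals.groupby("subclass").apply(_qf, include_groups=False)


def apply_quality_threshold(flags: pd.DataFrame,
                            threshold: float = DEFAULT_QUALITY_THRESHOLD
                            ) -> pd.DataFrame:
    """Exclude (sample, subclass) blocks whose quality fraction is too low.

    ``flags`` needs columns quality_fraction and included; excluded rows get
    reason "low_quality_fraction".
    """
    out = flags.copy()
    low = out["quality_fraction"] <= threshold
    out.loc[low, "included"] = False
    out["exclusion_reason"] = ""
    out.loc[low, "exclusion_reason"] = "low_quality_fraction"
    return out


def winsorize_5sd(values, n_sds: float = 5.0) -> np.ndarray:
    """Clamp values beyond mean +/- n_sds * SD to the boundary.

    Mean and SD (ddof=1) are computed once on the input, not iterated.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValueError("need at least 2 values")
    m, s = finite.mean(), finite.std(ddof=1)
    if s == 0:
        return x.copy()
    return np.clip(x, m - n_sds * s, m + n_sds * s)


def log_transform(table: pd.DataFrame, variables, policy: str = "offset",
                  offset: float | None = None) -> pd.DataFrame:
    """Replace listed columns by their natural logarithm.

    policy "strict" errors on non-positive values (naming variable and
    sample); "offset" adds a pseudo-count (default: half the smallest
    positive observed value of that variable); "drop" sets non-positive
    entries to NaN.
    """
    if policy not in ("strict", "offset", "drop"):
        raise ValueError(f"unknown log policy {policy!r}")
    out = table.copy()
    for var in variables:
        x = out[var].astype(float)
        nonpos = x[x.notna() & (x <= 0)]
        if policy == "strict" and not nonpos.empty:
            sample = nonpos.index[0]
            raise ValueError(
                f"non-positive value of {var!r} at sample {sample!r} "
                "under strict log policy")
        if policy == "offset" and not nonpos.empty:
            off = offset
            if off is None:
                positive = x[x > 0]
                if positive.empty:
                    raise ValueError(f"no positive values of {var!r} to set offset")
                off = positive.min() / 2.0
            x = x + off
        if policy == "drop":
            x = x.where(x > 0)
        out[var] = np.log(x)
    return out


# ---------------------------------------------------------------------------
# full curation pipeline


def profiles_from_extractions(extractions: dict, exclusions=None
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude + normalize every sample's extraction frame.

    ``extractions`` maps sample_id -> extraction frame.  Returns a long
    profile table (sample_id, subclass, shorthand, pct) and a per
    (sample_id, subclass) flag table (included, quality_fraction).
    """
    prof_rows, flag_rows = [], []
    for sid, sig in extractions.items():
        sig = exclude_analytes(sig, exclusions or [])
        qf = quality_fraction(sig)
        norm = normalize(sig)
        norm.insert(0, "sample_id", sid)
        prof_rows.append(norm)
        for subclass, g in norm.groupby("subclass"):
            flag_rows.append({"sample_id": sid, "subclass": subclass,
                              "included": bool(g["included"].all()),
                              "quality_fraction": float(qf[subclass])})
    profiles = pd.concat(prof_rows, ignore_index=True)
    flags = pd.DataFrame(flag_rows)
    return profiles, flags


def traits_from_profiles(profiles: pd.DataFrame, flags: pd.DataFrame
                         ) -> pd.DataFrame:
    """Derive glycosylation features per included (sample, subclass)."""
    rows = []
    included = {(r.sample_id, r.subclass) for r in flags.itertuples()
                if r.included}
    for (sid, subclass), g in profiles.groupby(["sample_id", "subclass"]):
        if (sid, subclass) not in included:
            continue
        prof = dict(zip(g["shorthand"], g["pct"]))
        tv = compute_traits(prof, subclass)
        row = {"sample_id": sid, "subclass": subclass}
        row.update(tv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def curate(extractions: dict, plates: pd.Series,
           config: CurationConfig | None = None) -> pd.DataFrame:
    """Run the full curation pipeline to a wide per-sample trait table.

    Returns one row per sample with columns ``{subclass}_{trait}`` (ComBat
    batch-corrected, winsorized; glycosylation features ln-transformed) plus
    QC columns.  ``plates`` maps sample_id -> plate label.
    """
    cfg = config or CurationConfig()
    profiles, flags = profiles_from_extractions(
        extractions, exclusions=cfg.excluded_analytes)
    flags = apply_quality_threshold(flags, cfg.quality_threshold)

    if cfg.combat_on == "glycoforms":
        wide = profiles.pivot_table(index="sample_id",
                                    columns=["subclass", "shorthand"],
                                    values="pct")
        adj, _ = combat_adjust(wide, plates.loc[wide.index])
        long = adj.stack(["subclass", "shorthand"], future_stack=True)
        profiles = long.rename("pct").reset_index()
        merged = profiles.merge(flags[["sample_id", "subclass", "included"]],
                                on=["sample_id", "subclass"])
        profiles["included"] = merged["included"]

    trait_long = traits_from_profiles(profiles, flags)
    wide = trait_long.pivot_table(index="sample_id", columns="subclass",
                                  values=TRAIT_NAMES + PER_GLYCAN_NAMES)
    wide.columns = [f"{sub}_{trait}" for trait, sub in wide.columns]

    if cfg.combat_on == "traits":
        cols = [c for c in wide.columns if wide[c].notna().sum() > 1]
        complete = wide[cols].dropna()
        if len(complete) >= 4 and plates.loc[complete.index].nunique() >= 2:
            adj, _ = combat_adjust(complete, plates.loc[complete.index])
            wide.loc[complete.index, cols] = adj

    n_clipped = {}
    for c in wide.columns:
        before = wide[c].to_numpy(dtype=float)
        finite = np.isfinite(before)
        if finite.sum() >= 2:
            after = winsorize_5sd(before, cfg.winsorize_sds)
            n_clipped[c] = int(np.sum(finite & (after != before)))
            wide[c] = after
    wide = log_transform(wide, list(wide.columns), policy=cfg.log_policy,
                         offset=cfg.log_offset)
    wide.attrs["n_clipped"] = n_clipped
    qc = flags.pivot_table(index="sample_id", columns="subclass",
                           values="quality_fraction")
    qc.columns = [f"{sub}_quality_fraction" for sub in qc.columns]
    return wide.join(qc)


def select_replicate_plate(plate_a: dict, plate_b: dict) -> str:
    """Pick the replicate plate with the higher median total signal.

    ``plate_a``/``plate_b`` map sample_id -> extraction frame; returns "a"
    or "b".
    """
    med_a = float(np.median([df["raw_intensity"].sum() for df in plate_a.values()]))
    med_b = float(np.median([df["raw_intensity"].sum() for df in plate_b.values()]))
    return "a" if med_a >= med_b else "b"
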