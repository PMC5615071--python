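"""Shared study configuration for the analysis scripts.

Every script regenerates data deterministically from STUDY_SEED, so the
scripts can be run independently and in any order; intermediate tables are
still written under results/ for inspection.
"""

from pathlib import Path

from iggfc.panel import build_panel
from iggfc.simulate import CohortConfig, simulate_cohort

STUDY_SEED = 2026

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

#: true effects of metabolic parameters on glycosylation features
#: (per ln-unit for log-scale variables, per mmol/L otherwise), mirroring
#: the inflammation/lipid directions the pipeline is meant to detect:
#: low galactosylation/sialylation and high fucosylation with inflammation,
#: higher galactosylation with HDLC, lower with TG, bisection up with glucose
TRUE_EFFECTS = {
    ("galactosylation", "crp"): -1.2,
    ("sialylation", "crp"): -0.25,
    ("fucosylation", "crp"): 0.4,
    ("galactosylation", "hdlc"): 2.0,
    ("galactosylation", "tg"): -1.0,
    ("bisection", "glucose"): 0.8,
}


def study_config() -> CohortConfig:
    return CohortConfig(
        n_individuals=384,          # 4 full 96-well plates
        n_families=130,
        rho_fam=0.2,
        effect_map=dict(TRUE_EFFECTS),
        seed=STUDY_SEED,
    )


def study_cohort(panel=None):
    panel = panel or build_panel()
    cohort, truth = simulate_cohort(study_config(), panel)
    return panel, cohort, truth
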