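"""Shared locations and run settings for the numbered analysis scripts.

Every script writes small summary tables to ``results/`` and bulky
intermediates (per-event tables) to ``scratch/``.  One seed drives the
whole analysis so each step is reproducible in isolation.
"""

from pathlib import Path

from picosize.fcm import CalibrationModel
from picosize.synthetic import DEFAULT_SEED

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
EVENTS_DIR = SCRATCH / "events"

SEED = DEFAULT_SEED
N_EVENTS_PEAK = 20_000
N_CELLS = 100_000
READ_DEPTH = 50_000
VOLUME_ML = 0.1

# calibration used both to generate FSC signals and to size populations;
# the monotone log-linear form is the study default
CALIBRATION = CalibrationModel(form="log_linear")
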