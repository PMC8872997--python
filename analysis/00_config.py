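"""Shared settings for the numbered analysis scripts.

One study-shaped synthetic cohort (n = 32,256, 42 asymmetry indexes, two
polygenic scores) is simulated once by ``01_simulate_cohort.py`` and
reused by every later stage; all outputs land under ``results/``.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_PREFIX = str(RESULTS / "cohort")
SEED = 2026
N_PERMUTATIONS = 2000
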