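"""One-time calibration of the default interaction-curve tables.

The migration-curve magnitude (m_max), optimum (theta) and steepness (p),
together with the activation-pulse width, were tuned against the four
published simulation outputs (MMP-9 peaks of 80 and 220 pg/uL for the
amplitude-15 and -60 stimuli; macrophage peak day 3 and MMP-9 peak day 4
under the amplitude-30 stimulus) and then frozen into
src/lvremodel/data/curves.  Run this script to regenerate the tables.
"""
from pathlib import Path

from lvremodel import build_curve_set

# frozen calibration outcome (see scratch/explore.py sweeps + least_squares)
M_MAX = 2845.0     # cells/mm^3/day at the chemotactic optimum
THETA = 2.239      # pg/uL, TGF-beta1 optimum of monocyte chemotaxis
SHAPE_P = 4.0      # steepness of the biphasic window
PULSE_WIDTH = 0.33  # log-days, default StimulusProfile width

if __name__ == "__main__":
    curves = build_curve_set(M_MAX, THETA, SHAPE_P)
    out = Path(__file__).resolve().parents[1] / "src" / "lvremodel" / "data" / "curves"
    curves.to_dir(out)
    print(f"wrote calibrated curve tables to {out}")
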