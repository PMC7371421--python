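"""Published reference values for hSlo1 C-linker scramble constructs.

Half-activation voltages (mV) from Boltzmann fits to patch-clamp G-V and
Q-V relations of the wild-type channel and the C-linker sequence-scramble
mutants, in the full-length channel (0 and 100 uM intracellular Ca2+) and
the gating-ring-deleted Core-MT construct (0 Ca2+). These constants are
inputs for worked examples and for building synthetic stand-in datasets;
nothing in the analysis code depends on them.
"""

from __future__ import annotations

__all__ = ["GV_V05_MV", "GV_V05_SE_MV", "QV_BOLTZMANN", "CLINKER_RESIDUES"]

#: G-V half-activation voltages (mV): construct -> condition -> V0.5
GV_V05_MV: dict[str, dict[str, float]] = {
    "WT":        {"full_0Ca": 183.4, "full_100Ca": 0.2,   "coreMT_0Ca": 235.0},
    "K0":        {"full_0Ca": 89.6,  "full_100Ca": -66.7, "coreMT_0Ca": 192.6},
    "K0_Y330G":  {"full_0Ca": 169.8, "full_100Ca": 47.5},
    "K1":        {"full_0Ca": 136.2, "full_100Ca": -4.2},
    "K2":        {"full_0Ca": 195.5, "full_100Ca": 59.0,  "coreMT_0Ca": 263.5},
    "K4":        {"full_0Ca": 94.6,  "full_100Ca": -50.4},
    "K7":        {"full_0Ca": 48.7,  "full_100Ca": -63.7, "coreMT_0Ca": 167.5},
}

#: published standard errors (mV) where reported in figure captions
GV_V05_SE_MV: dict[str, dict[str, float]] = {
    "WT":       {"full_0Ca": 3.2, "coreMT_0Ca": 3.1},
    "K0":       {"full_0Ca": 3.5, "coreMT_0Ca": 3.8},
    "K0_Y330G": {"full_0Ca": 5.0},
    "K2":       {"full_0Ca": 3.5, "coreMT_0Ca": 4.0},
    "K7":       {"full_0Ca": 4.7, "coreMT_0Ca": 4.2},
}

#: Q-V Boltzmann parameters (V0.5 mV, slope factor mV) from on-gating currents
QV_BOLTZMANN: dict[str, dict[str, float]] = {
    "WT_full":   {"V05": 159.1, "V05_se": 6.5, "b": 49.0, "b_se": 5.9},
    "K0_full":   {"V05": 161.9, "V05_se": 9.2, "b": 51.6, "b_se": 8.5},
    "WT_coreMT": {"V05": 138.0, "V05_se": 3.1, "b": 51.3, "b_se": 2.8},
    "K0_coreMT": {"V05": 154.7, "V05_se": 6.8, "b": 50.1, "b_se": 5.6},
}

#: hSlo1 author numbering of the C-linker (S6 end to RCK1 N-lobe start)
CLINKER_RESIDUES = range(329, 344)
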