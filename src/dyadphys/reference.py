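"""Reference population parameters of the emulated study conditions.

The package models a two-condition dyadic experiment — personal (PC) versus
impersonal (IC) communication before a one-shot investment game, n = 14 per
condition — whose outcome structure is summarized here: per-condition mean
and SD of each baseline-normalized physiological index, and the empirical
frequency tables of the trust-game decisions. The synthetic cohort generator
treats these as its default population targets, and the inferential layer
can recompute the between-condition tests directly from them.

All indices except pupil dilation are communication-phase values expressed
as a ratio to the subject's own 5-min resting baseline (dimensionless);
pupil dilation is the baseline-subtracted mean diameter change in mm.
"""

from __future__ import annotations

#: Canonical order of the ten per-subject indices.
INDEX_NAMES = (
    "heart_rate",
    "emg_corrugator",
    "skin_conductance",
    "alpha_asymmetry",
    "slow_alpha",
    "beta",
    "lf_hf",
    "pupil_dilation",
    "nn50",
    "rmssd",
)

#: Human-readable labels used in reports.
INDEX_LABELS = {
    "heart_rate": "Heart rate",
    "emg_corrugator": "EMG corrugator",
    "skin_conductance": "Skin conductance",
    "alpha_asymmetry": "EEG Alpha Asymmetry",
    "slow_alpha": "EEG Slow Alpha waves",
    "beta": "EEG Beta waves",
    "lf_hf": "LF/HF",
    "pupil_dilation": "Pupil dilation",
    "nn50": "NN50",
    "rmssd": "RMSSD",
}

#: Per-condition population (mean, sd) of each index, n = 14 per condition.
INDEX_STATS = {
    "heart_rate":       {"PC": (1.169537, 0.282227), "IC": (1.492253, 0.514155)},
    "emg_corrugator":   {"PC": (1.308825, 0.296176), "IC": (1.704306, 0.590298)},
    "skin_conductance": {"PC": (1.310103, 0.305998), "IC": (1.744871, 0.644443)},
    "alpha_asymmetry":  {"PC": (1.619759, 0.331382), "IC": (2.034656, 0.613816)},
    "slow_alpha":       {"PC": (1.655140, 0.281301), "IC": (1.996572, 0.529739)},
    "beta":             {"PC": (1.270383, 0.331340), "IC": (1.656981, 0.619189)},
    "lf_hf":            {"PC": (1.230078, 0.272284), "IC": (1.474582, 0.429780)},
    "pupil_dilation":   {"PC": (0.4252, 0.09369),    "IC": (0.5309, 0.16404)},
    "nn50":             {"PC": (0.699334, 0.132247), "IC": (0.603127, 0.173188)},
    "rmssd":            {"PC": (0.674883, 0.306916), "IC": (0.372111, 0.422183)},
}

N_PER_CONDITION = 14

#: Empirical frequencies of the amount (Euros) sent by the proposer.
TRUST_FREQUENCIES = {
    "PC": {100: 0, 500: 1, 1000: 7, 1500: 4, 2000: 2},
    "IC": {100: 2, 500: 3, 1000: 3, 1500: 2, 2000: 4},
}

#: Empirical frequencies of the fraction of the tripled amount returned.
RECIPROCITY_FREQUENCIES = {
    "PC": {0.25: 1, 0.5: 6, 0.75: 7},
    "IC": {0.25: 3, 0.5: 9, 0.75: 2},
}
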