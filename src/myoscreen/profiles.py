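"""Versioned generator default profiles.

These are *simulation defaults* for the synthetic-data generator, seeded from
published species means for adult ventricular cardiomyocytes (sarcomere length,
% shortening, transient kinetics, morphology) and from dose-response studies of
dobutamine, omecamtiv mecarbil (OM) and mavacamten. They are generator
parameters, not measurements: the kinetic time constants were solved offline on
a dense grid so that a noiseless generated beat reproduces the target TTB90
(and, where the two-exponential beat family permits, TTP90).
"""

from __future__ import annotations

import copy

PROFILE_VERSION = "1.0"

#: Contraction (sarcomere-length) transient defaults per species.
#: ``baseline_um`` is resting sarcomere length; ``amplitude_frac`` is the
#: fractional peak shortening (0.0367 -> 3.67 %). ``target_*`` fields record
#: the kinetic intervals the taus were solved against (seconds).
SPECIES = {
    "rat": dict(
        baseline_um=1.826,
        amplitude_frac=0.0367,
        tau_rise_s=0.018015,
        tau_decay_s=0.072059,
        pacing_hz=1.0,
        target_ttb90_s=0.182,
        target_ttp90_s=0.056,  # unreachable for this beat family; actual ~0.016
    ),
    "mouse": dict(
        baseline_um=1.80,  # generator default; resting SL not tabulated for mouse
        amplitude_frac=0.02539,
        tau_rise_s=0.030189,
        tau_decay_s=0.120758,
        pacing_hz=1.0,
        target_ttb90_s=0.305,
        target_ttp90_s=0.048,
    ),
    "guinea_pig": dict(
        baseline_um=1.776,
        amplitude_frac=0.05213,
        tau_rise_s=0.062062,
        tau_decay_s=0.248246,
        pacing_hz=0.5,
        target_ttb90_s=0.627,
        target_ttp90_s=0.228,
    ),
}

#: Ratiometric Ca2+ (Fura) transient defaults. Baseline ratio is 1.0 by
#: construction; ``amplitude_frac`` is F/F0 - 1.
SPECIES_CA = {
    "rat": dict(
        baseline_ratio=1.0,
        amplitude_frac=0.136,
        tau_rise_s=0.019409,
        tau_decay_s=0.076309,
        pacing_hz=1.0,
        target_ttp90_s=0.017,
        target_ttb90_s=0.193,
    ),
    "mouse": dict(
        baseline_ratio=1.0,
        amplitude_frac=0.143,
        tau_rise_s=0.016560,
        tau_decay_s=0.171629,
        pacing_hz=1.0,
        target_ttp90_s=0.021,
        target_ttb90_s=0.411,
    ),
    "guinea_pig": dict(
        baseline_ratio=1.0,
        amplitude_frac=0.196,
        tau_rise_s=0.189916,  # rise:decay 1:1; TTP90/TTB90 ratio at family limit
        tau_decay_s=0.189916,
        pacing_hz=0.5,
        target_ttp90_s=0.083,
        target_ttb90_s=0.564,
    ),
}

#: Cell-geometry defaults used by the field-image generator (microns).
MORPHOLOGY = {
    "rat": dict(length_um=133.3, width_um=37.39, sarcomere_um=1.826),
    "guinea_pig": dict(length_um=161.0, width_um=42.69, sarcomere_um=1.776),
}

#: Dose-response fixture profiles for the three binding-equation forms.
#: ``ec50_um`` and the maximal-effect parameters come from published fits;
#: doses are the generator's log-spaced sampling grids (micromolar).
COMPOUNDS = {
    "mavacamten_pct": dict(
        equation_form="full_inhibition", y0=3.67, bm=None, ec50_um=0.8,
        dose_range_um=(0.03, 10.0), n_doses=6,
    ),
    "mavacamten_ttp90": dict(
        equation_form="decrease", y0=0.056, bm=0.010, ec50_um=0.37,
        dose_range_um=(0.03, 10.0), n_doses=6,
    ),
    "dobutamine_ttp90": dict(
        equation_form="decrease", y0=0.056, bm=0.020, ec50_um=0.14,
        dose_range_um=(0.01, 3.0), n_doses=6,
    ),
    "dobutamine_ttb90": dict(
        equation_form="decrease", y0=0.182, bm=0.050, ec50_um=0.21,
        dose_range_um=(0.01, 3.0), n_doses=6,
    ),
    "om_pct": dict(
        # Bm/y0 = 2.16 -> +216 % maximal increase in % shortening
        equation_form="increase", y0=2.0, bm=4.32, ec50_um=3.1,
        dose_range_um=(0.1, 10.0), n_doses=6,
    ),
    "om_ttp90": dict(
        equation_form="increase", y0=0.056, bm=0.098, ec50_um=1.8,
        dose_range_um=(0.1, 10.0), n_doses=6,
    ),
    "om_ttb90": dict(
        equation_form="increase", y0=0.182, bm=0.3676, ec50_um=2.2,
        dose_range_um=(0.1, 10.0), n_doses=6,
    ),
}


def species_profile(name: str, signal_kind: str = "sarcomere_length") -> dict:
    """Return a copy of a species transient profile.

    Parameters
    ----------
    name : one of ``rat``, ``mouse``, ``guinea_pig``.
    signal_kind : ``sarcomere_length`` (contraction) or ``ca_ratio``.
    """
    table = SPECIES_CA if signal_kind == "ca_ratio" else SPECIES
    if name not in table:
        raise KeyError(
            f"unknown species profile {name!r}; available: {sorted(table)}"
        )
    return copy.deepcopy(table[name])


def compound_profile(name: str) -> dict:
    """Return a copy of a dose-response compound fixture profile."""
    if name not in COMPOUNDS:
        raise KeyError(
            f"unknown compound profile {name!r}; available: {sorted(COMPOUNDS)}"
        )
    return copy.deepcopy(COMPOUNDS[name])
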