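"""Synthetic data generation for the contractility pipeline.

Every downstream stage (transient extraction, image analysis, hierarchical
statistics, pharmacology) is exercised against data produced here with known
ground truth: paced contraction / Ca2+ transients with species-level kinetics,
nested cell-within-preparation datasets with a specified intra-class
correlation, dose-response datasets following the three binding-equation
forms, and rendered fields of rod-shaped striated cells.

The beat deflection is the two-exponential product

    g(t) = k * (1 - exp(-(t - ts)/tau_rise)) * exp(-(t - ts)/tau_decay)

with ``k`` chosen analytically so the peak deflection equals
``amplitude_frac * baseline``. All randomness is driven by
``numpy.random.Generator`` seeded explicitly; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .transients import Transient


class ConfigurationError(ValueError):
    """A generator spec violates one of its invariants; names the field."""


# ---------------------------------------------------------------------------
# transient generator
# ---------------------------------------------------------------------------

@dataclass
class TransientModel:
    """Parameters of a paced single-cell transient.

    ``polarity`` is ``"downward"`` for contraction (sarcomere or cell length
    shortens) and ``"upward"`` for Ca2+ ratio transients.
    """

    baseline_level: float = 1.826     # um (or dimensionless ratio, 1.0 for Ca)
    amplitude_frac: float = 0.0367    # peak deflection as fraction of baseline
    t0: float = 0.1                   # stimulus onset within the record, s
    tau_rise: float = 0.018015        # s
    tau_decay: float = 0.072059       # s
    pacing_hz: float = 1.0
    duration_s: float = 10.0
    sample_hz: float = 1000.0
    noise_sd: float = 0.0             # signal units
    polarity: str = "downward"
    signal_kind: str = "sarcomere_length"

    def validate(self) -> None:
        if not (0.0 <= self.amplitude_frac < 1.0):
            raise ConfigurationError("amplitude_frac must be in [0, 1)")
        if self.tau_rise <= 0:
            raise ConfigurationError("tau_rise must be > 0")
        if self.tau_decay <= 0:
            raise ConfigurationError("tau_decay must be > 0")
        if self.pacing_hz <= 0:
            raise ConfigurationError("pacing_hz must be > 0")
        if self.t0 < 0 or self.t0 >= 1.0 / self.pacing_hz:
            raise ConfigurationError("t0 must lie within one pacing period")
        if self.sample_hz < 100:
            raise ConfigurationError("sample_hz must be >= 100")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.polarity not in ("downward", "upward"):
            raise ConfigurationError("polarity must be 'downward' or 'upward'")
        if self.baseline_level <= 0:
            raise ConfigurationError("baseline_level must be > 0")


def beat_kernel_peak(tau_rise: float, tau_decay: float) -> tuple[float, float]:
    """Analytic peak time and height of (1-exp(-t/tr))*exp(-t/td).

    The stationary point is t* = tr*ln(1 + td/tr); the peak height follows by
    substitution. Used to normalise beats to an exact fractional amplitude.
    """
    tp = tau_rise * np.log1p(tau_decay / tau_rise)
    gmax = (tau_decay / (tau_rise + tau_decay)) * (
        tau_rise / (tau_rise + tau_decay)
    ) ** (tau_rise / tau_decay)
    return tp, gmax


def beat_waveform(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-normalised beat deflection at times ``t`` (t=0 is stimulus)."""
    _, gmax = beat_kernel_peak(tau_rise, tau_decay)
    g = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    g[pos] = (1.0 - np.exp(-tp / tau_rise)) * np.exp(-tp / tau_decay) / gmax
    return g


def gen_transient(model: TransientModel, seed: int | None = 0) -> Transient:
    """Generate one cell's paced transient record.

    Returns a :class:`~myoscreen.transients.Transient` spanning ``duration_s``
    at ``sample_hz`` with ``floor(duration_s * pacing_hz)`` stimulated beats;
    the noiseless peak deflection of each beat equals
    ``amplitude_frac * baseline_level`` exactly (up to beat-tail overlap).
    """
    model.validate()
    rng = np.random.default_rng(seed)
    n = int(round(model.duration_s * model.sample_hz))
    t = np.arange(n) / model.sample_hz
    period = 1.0 / model.pacing_hz
    n_beats = int(np.floor(model.duration_s * model.pacing_hz))
    stim = model.t0 + period * np.arange(n_beats)

    amp = model.amplitude_frac * model.baseline_level
    deflection = np.zeros(n)
    for ts in stim:
        deflection += amp * beat_waveform(t - ts, model.tau_rise, model.tau_decay)
    sign = -1.0 if model.polarity == "downward" else 1.0
    signal = model.baseline_level + sign * deflection
    if model.noise_sd > 0:
        signal = signal + rng.normal(0.0, model.noise_sd, size=n)
    return Transient(
        time_s=t,
        signal=signal,
        signal_kind=model.signal_kind,
        pacing_hz=model.pacing_hz,
        stimulus_times_s=stim,
    )


# ---------------------------------------------------------------------------
# nested (cell-within-preparation) datasets
# ---------------------------------------------------------------------------

@dataclass
class NestedDesign:
    """Two-level design: preparations (clusters) and cells within them.

    The implied intra-class correlation is sigma_b^2/(sigma_b^2+sigma_w^2).
    """

    n_preps: int
    cells_per_prep: int | list[int]
    grand_mean: float
    sigma_between: float
    sigma_within: float
    seed: int = 0

    def validate(self) -> None:
        if self.n_preps < 2:
            raise ConfigurationError("n_preps must be >= 2 (ICC undefined otherwise)")
        if self.sigma_between < 0:
            raise ConfigurationError("sigma_between must be >= 0")
        if self.sigma_within <= 0:
            raise ConfigurationError("sigma_within must be > 0")
        sizes = self.cluster_sizes()
        if any(m < 1 for m in sizes):
            raise ConfigurationError("cells_per_prep entries must be >= 1")
        if len(sizes) != self.n_preps:
            raise ConfigurationError("cells_per_prep list must have n_preps entries")

    def cluster_sizes(self) -> list[int]:
        if isinstance(self.cells_per_prep, int):
            return [self.cells_per_prep] * self.n_preps
        return list(self.cells_per_prep)

    @property
    def icc(self) -> float:
        b2, w2 = self.sigma_between**2, self.sigma_within**2
        return b2 / (b2 + w2)


def gen_nested_dataset(design: NestedDesign, condition: str = "baseline"):
    """Draw a nested dataset: prep means ~ N(mu, sb^2), cells ~ N(m_i, sw^2)."""
    from .hstats import NestedDataset  # deferred: hstats imports this module

    design.validate()
    rng = np.random.default_rng(design.seed)
    sizes = design.cluster_sizes()
    values, clusters = [], []
    prep_means = rng.normal(design.grand_mean, design.sigma_between, size=design.n_preps)
    for i, (m_i, size) in enumerate(zip(prep_means, sizes)):
        values.append(rng.normal(m_i, design.sigma_within, size=size))
        clusters.append(np.full(size, i))
    return NestedDataset(
        values=np.concatenate(values),
        cluster_ids=np.concatenate(clusters),
        condition=condition,
    )


# ---------------------------------------------------------------------------
# dose-response datasets
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseDesign:
    """Per-cell responses whose dose means follow a binding equation."""

    equation_form: str                 # increase | decrease | full_inhibition
    y0: float
    ec50_um: float
    doses_um: list[float] = field(default_factory=list)
    bm: float | None = None            # unused for full_inhibition
    cells_per_dose: int = 20
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.equation_form not in ("increase", "decrease", "full_inhibition"):
            raise ConfigurationError(
                "equation_form must be increase, decrease or full_inhibition"
            )
        if self.ec50_um <= 0:
            raise ConfigurationError("ec50_um must be > 0")
        if any(d < 0 for d in self.doses_um):
            raise ConfigurationError("doses_um must be >= 0")
        if len(set(self.doses_um)) < 4:
            raise ConfigurationError("doses_um must contain >= 4 distinct doses")
        if self.equation_form != "full_inhibition" and self.bm is None:
            raise ConfigurationError("bm is required for increase/decrease forms")
        if self.cells_per_dose < 1:
            raise ConfigurationError("cells_per_dose must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def gen_dose_response(design: DoseResponseDesign):
    """Per-cell responses at each dose (one pseudo-preparation per dose)."""
    from .hstats import NestedDataset
    from .pharm import binding_curve  # deferred to avoid an import cycle

    design.validate()
    rng = np.random.default_rng(design.seed)
    values, clusters, doses = [], [], []
    for i, dose in enumerate(design.doses_um):
        mean = binding_curve(
            design.equation_form, np.asarray([dose]), design.y0,
            design.bm, design.ec50_um,
        )[0]
        draws = mean + rng.normal(0.0, design.noise_sd, size=design.cells_per_dose) \
            if design.noise_sd > 0 else np.full(design.cells_per_dose, mean)
        values.append(draws)
        clusters.append(np.full(design.cells_per_dose, i))
        doses.append(np.full(design.cells_per_dose, dose))
    return NestedDataset(
        values=np.concatenate(values),
        cluster_ids=np.concatenate(clusters),
        condition="dose_response",
        dose_um=np.concatenate(doses),
    )


def log_spaced_doses(lo_um: float, hi_um: float, n: int, include_zero: bool = True) -> list[float]:
    """Log-spaced dose grid in micromolar, optionally anchored at dose 0."""
    doses = list(np.geomspace(lo_um, hi_um, n))
    return ([0.0] + doses) if include_zero else doses


# ---------------------------------------------------------------------------
# striated rod-cell field images
# ---------------------------------------------------------------------------

@dataclass
class CellSpec:
    """One rendered rod cell: position is the center in microns (row, col)."""

    center_um: tuple[float, float]
    length_um: float = 133.3
    width_um: float = 37.39
    orientation_rad: float = 0.0       # angle of the long axis from the column axis
    striation_period_um: float = 1.826
    striation_contrast: float = 0.5    # 0..1 modulation depth


@dataclass
class FieldImageSpec:
    """A calibrated grayscale field of striated rod cells."""

    image_size_px: tuple[int, int] = (512, 512)
    calibration_um_per_px: float = 0.2
    cells: list[CellSpec] = field(default_factory=list)
    background_level: float = 100.0
    cell_level: float = 1000.0         # mean interior intensity above zero
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.calibration_um_per_px <= 0:
            raise ConfigurationError("calibration_um_per_px must be > 0")
        rows_um = self.image_size_px[0] * self.calibration_um_per_px
        cols_um = self.image_size_px[1] * self.calibration_um_per_px
        for i, c in enumerate(self.cells):
            if c.striation_period_um >= c.length_um:
                raise ConfigurationError(
                    f"cells[{i}].striation_period_um must be < length_um"
                )
            if not (0.0 <= c.striation_contrast <= 1.0):
                raise ConfigurationError(
                    f"cells[{i}].striation_contrast must be in [0, 1]"
                )
            half_diag = 0.5 * float(np.hypot(c.length_um, c.width_um))
            r, q = c.center_um
            if (r - half_diag < 0 or q - half_diag < 0
                    or r + half_diag > rows_um or q + half_diag > cols_um):
                raise ConfigurationError(
                    f"cells[{i}] extends outside the image bounds"
                )


def gen_field_image(spec: FieldImageSpec):
    """Render the field: rounded-rectangle rods with sinusoidal striations.

    Interior intensity is ``cell_level * (1 + contrast*cos(2*pi*u/period))/ (1+contrast)``
    scaled so the mean interior intensity is ``cell_level``; ``u`` is the
    coordinate along the cell's long axis, so the striation wave vector is
    axial. Overlapping cells are permitted (the cell finder must cope).
    """
    from .imaging import FieldImage  # deferred: imaging imports nothing from here

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size_px
    cal = spec.calibration_um_per_px
    rr, cc = np.mgrid[0:rows, 0:cols]
    r_um = rr * cal
    c_um = cc * cal
    img = np.full((rows, cols), float(spec.background_level))
    for cell in spec.cells:
        r0, c0 = cell.center_um
        ct, st = np.cos(cell.orientation_rad), np.sin(cell.orientation_rad)
        u = (c_um - c0) * ct + (r_um - r0) * st          # along long axis, um
        v = -(c_um - c0) * st + (r_um - r0) * ct         # across, um
        corner = 0.25 * cell.width_um
        du = np.maximum(np.abs(u) - (cell.length_um / 2 - corner), 0.0)
        dv = np.maximum(np.abs(v) - (cell.width_um / 2 - corner), 0.0)
        inside = np.hypot(du, dv) <= corner
        stri = 1.0 + cell.striation_contrast * np.cos(
            2.0 * np.pi * u / cell.striation_period_um
        )
        img[inside] = spec.background_level + spec.cell_level * stri[inside]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return FieldImage(pixels=img, calibration_um_per_px=cal)


# ---------------------------------------------------------------------------
# external interfaces (tidy CSV / TIFF + sidecar)
# ---------------------------------------------------------------------------

TRACE_COLUMNS = ["cell_id", "prep_id", "condition", "dose_um", "time_s", "signal", "signal_kind"]


def transients_to_frame(records: list[tuple[dict, Transient]]) -> pd.DataFrame:
    """Stack (metadata, Transient) pairs into the tidy long trace format.

    ``metadata`` must carry ``cell_id``/``prep_id``/``condition`` and may carry
    ``dose_um``.
    """
    frames = []
    for meta, tr in records:
        frames.append(pd.DataFrame({
            "cell_id": meta["cell_id"],
            "prep_id": meta["prep_id"],
            "condition": meta.get("condition", "baseline"),
            "dose_um": meta.get("dose_um", 0.0),
            "time_s": tr.time_s,
            "signal": tr.signal,
            "signal_kind": tr.signal_kind,
        }))
    if not frames:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def gen_nested_transient_records(
    species_profile: dict,
    n_preps: int,
    cells_per_prep: int,
    seed: int,
    sigma_between_frac: float = 0.106,
    sigma_within_frac: float = 0.222,
    signal_kind: str = "sarcomere_length",
    condition: str = "baseline",
    noise_sd: float = 0.0,
    duration_s: float = 10.0,
) -> list[tuple[dict, Transient]]:
    """Full nested record set: per-cell amplitudes drawn two-level, then traces.

    The default between/within fractions (of the mean amplitude) reproduce an
    ICC of ~0.185, the clustering level reported for rat % sarcomere
    shortening. Each cell's trace is generated from its own amplitude so a
    downstream analysis recovers the nested structure.
    """
    ss = np.random.SeedSequence(seed)
    design_seed, trace_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    amp_mean = species_profile["amplitude_frac"]
    design = NestedDesign(
        n_preps=n_preps,
        cells_per_prep=cells_per_prep,
        grand_mean=amp_mean,
        sigma_between=sigma_between_frac * amp_mean,
        sigma_within=sigma_within_frac * amp_mean,
        seed=design_seed,
    )
    nested = gen_nested_dataset(design, condition=condition)
    baseline = species_profile.get("baseline_um", species_profile.get("baseline_ratio", 1.0))
    polarity = "upward" if signal_kind == "ca_ratio" else "downward"
    records = []
    trace_rng = np.random.SeedSequence(trace_seed).spawn(len(nested.values))
    for j, (amp, prep) in enumerate(zip(nested.values, nested.cluster_ids)):
        model = TransientModel(
            baseline_level=baseline,
            amplitude_frac=float(np.clip(amp, 0.0, 0.99)),
            tau_rise=species_profile["tau_rise_s"],
            tau_decay=species_profile["tau_decay_s"],
            pacing_hz=species_profile["pacing_hz"],
            duration_s=duration_s,
            noise_sd=noise_sd,
            polarity=polarity,
            signal_kind=signal_kind,
        )
        tr = gen_transient(model, seed=int(trace_rng[j].generate_state(1)[0] % (2**31)))
        meta = {"cell_id": f"p{int(prep)}c{j}", "prep_id": f"prep{int(prep)}",
                "condition": condition}
        records.append((meta, tr))
    return records


def write_field_image(image, path: str | Path) -> None:
    """Write a 16-bit grayscale TIFF plus a JSON calibration sidecar."""
    import tifffile

    path = Path(path)
    px = np.clip(image.pixels, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, px)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"calibration_um_per_px": image.calibration_um_per_px}, indent=2,
    ))


def asdict(obj) -> dict:
    """Plain-dict view of any generator spec dataclass (for config logging)."""
    return dataclasses.asdict(obj)
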