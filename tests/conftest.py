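import numpy as np
import pytest

import myoscreen as ms


@pytest.fixture(scope="session")
def rat_profile():
    return ms.species_profile("rat")


@pytest.fixture(scope="session")
def rat_model(rat_profile):
    """Noiseless rat default transient model (10 s at 1 Hz, 1 kHz sampling)."""
    return ms.TransientModel(
        baseline_level=rat_profile["baseline_um"],
        amplitude_frac=rat_profile["amplitude_frac"],
        tau_rise=rat_profile["tau_rise_s"],
        tau_decay=rat_profile["tau_decay_s"],
        pacing_hz=rat_profile["pacing_hz"],
    )


@pytest.fixture(scope="session")
def rat_trace(rat_model):
    return ms.gen_transient(rat_model, seed=0)


@pytest.fixture(scope="session")
def rat_cell_image():
    """One noiseless rat rod (133.3 x 37.39 um, 1.826 um striations) at 0.2 um/px."""
    spec = ms.FieldImageSpec(
        image_size_px=(1024, 1024),
        calibration_um_per_px=0.2,
        cells=[ms.CellSpec(center_um=(102.4, 102.4), orientation_rad=0.3)],
        seed=0,
    )
    return ms.gen_field_image(spec)


@pytest.fixture(scope="session")
def rat_cell_mask(rat_cell_image):
    masks = ms.find_cells(rat_cell_image)
    assert len(masks) == 1
    return masks[0]


def dense_grid_crossings(tau_rise, tau_decay, fs=10_000.0, tmax=10.0):
    """Independent dense-grid oracle for TTP90 / TTB90 of the beat kernel.

    Evaluates g(t) = (1-exp(-t/tr))*exp(-t/td) on a 10 kHz grid and locates
    the 10%/90% rising crossings and the 90%-recovery crossing by linear
    interpolation, entirely independently of the package's fitting code.
    """
    t = np.arange(0.0, tmax, 1.0 / fs)
    g = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
    ip = int(np.argmax(g))
    gmax = g[ip]
    tp = t[ip]

    def crossing(seg_t, seg_g, level, rising):
        idx = np.nonzero(seg_g >= level if rising else seg_g <= level)[0][0]
        if idx == 0:
            return seg_t[0]
        f = (level - seg_g[idx - 1]) / (seg_g[idx] - seg_g[idx - 1])
        return seg_t[idx - 1] + f * (seg_t[idx] - seg_t[idx - 1])

    t10 = crossing(t[: ip + 1], g[: ip + 1], 0.1 * gmax, True)
    t90 = crossing(t[: ip + 1], g[: ip + 1], 0.9 * gmax, True)
    trec = crossing(t[ip:], g[ip:], 0.1 * gmax, False)
    return t90 - t10, trec - tp
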