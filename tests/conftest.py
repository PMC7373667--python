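import numpy as np
import pytest

from clotwave.io_formats import KineticCurve
from clotwave.simulate import ClotKinetics
from clotwave.waveform import DetectionConfig

SAMPLING = (12.0, 3600.0)


@pytest.fixture
def cfg() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def pnp_kin() -> ClotKinetics:
    """Noise-free kinetics matching the pooled-normal-plasma defaults."""
    return ClotKinetics(lag_s=600.0, rise_rate_au_per_min=0.03,
                        max_rise_au=0.18, noise_sd_au=0.0)


def make_curve(absorbances, interval=12.0, well_id="W0") -> KineticCurve:
    a = np.asarray(absorbances, dtype=float)
    t = np.arange(len(a)) * interval
    return KineticCurve(times=t, absorbances=a, well_id=well_id)


def recovery_grid(t_rise_min_s: float = 144.0, extra_max_rise=()):
    """(lag_s, rate, max_rise) triples spanning the published kinetic ranges.

    Lags 0.7-24 min and clotting rates 0.006-0.09 AU/min; each rate is
    paired with a max rise keeping the growth phase at least
    ``t_rise_min_s`` long (plus any ``extra_max_rise`` levels), and
    combinations whose onset would precede the baseline window or whose
    plateau would overrun the record are skipped.
    """
    out = []
    for lag_min in (0.7, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0,
                    12.0, 14.0, 16.0, 18.0, 20.0, 22.0, 24.0):
        for rate in (0.006, 0.008, 0.01, 0.015, 0.02, 0.03, 0.04,
                     0.05, 0.06, 0.07, 0.08, 0.09):
            levels = {max(0.18, rate * t_rise_min_s / 60.0), *extra_max_rise}
            for max_rise in sorted(levels):
                t_rise = max_rise / rate * 60.0
                lag_s = lag_min * 60.0
                if t_rise < t_rise_min_s:
                    continue
                if lag_s < 0.15 * t_rise + 48.0:
                    continue
                if lag_s + t_rise > 3300.0:
                    continue
                out.append((lag_s, rate, max_rise))
    return out
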