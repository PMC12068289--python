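"""Synthetic cohorts at the summary level (quadrant tables, subject values).

Two generators support the statistical machinery:

* :func:`simulate_quadrant_pairs` builds paired per-(subject, quadrant)
  SUV_diff / RPI values with a *designed* population correlation.  The signal
  component is a fixed quadrant-mean profile (posterior > left > right >
  anterior, shared up to scale by both modalities, as on the imaging side);
  independent Gaussian subject noise is added on top.  The variance is
  partitioned so that the population Pearson correlation over (quadrant,
  subject) pairs equals ``r_design`` exactly:

      var(signal) / [var(signal) + var(noise)] = r_design

  in each modality (with perfectly collinear profiles).  ``r_design = 0``
  degenerates to flat profiles with pure noise — the null cohort.

* :func:`simulate_mas_values` draws per-subject MAS cumulative uptake values
  with a prescribed number of subjects above/below a threshold (strictly, so
  the high/low classification of the cohort is known by construction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError
from .segmentation import QUADRANTS

__all__ = ["simulate_quadrant_pairs", "simulate_mas_values", "simulate_group_values"]

#: default quadrant profiles (posterior-dominant, as in the analysis defaults)
SUV_PROFILE = {"posterior": 0.70, "left": 0.60, "right": 0.50, "anterior": 0.40}
RPI_PROFILE = {"posterior": 0.45, "left": 0.40, "right": 0.35, "anterior": 0.30}


def simulate_quadrant_pairs(n_subjects: int, r_design: float, rng: np.random.Generator,
                            suv_profile: dict | None = None,
                            rpi_profile: dict | None = None) -> pd.DataFrame:
    """Paired quadrant-level (suv_diff, rpi) values with population r = r_design."""
    if not (0.0 <= r_design <= 1.0):
        raise ConfigError("r_design must lie in [0, 1]")
    suv_profile = dict(suv_profile or SUV_PROFILE)
    rpi_profile = dict(rpi_profile or RPI_PROFILE)
    a = np.array([suv_profile[q] for q in QUADRANTS])
    b = np.array([rpi_profile[q] for q in QUADRANTS])
    v_a, v_b = a.var(), b.var()
    if r_design == 0.0:
        a = np.full_like(a, a.mean())
        b = np.full_like(b, b.mean())
        sd_e, sd_f = np.sqrt(v_a), np.sqrt(v_b)
    else:
        k = (1.0 - r_design) / r_design
        sd_e, sd_f = np.sqrt(v_a * k), np.sqrt(v_b * k)
    rows = []
    for s in range(n_subjects):
        e = rng.normal(0.0, sd_e, size=4)
        f = rng.normal(0.0, sd_f, size=4)
        for qi, q in enumerate(QUADRANTS):
            rows.append({"subject": f"S{s:02d}", "quadrant": q,
                         "suv_diff": a[qi] + e[qi], "rpi": b[qi] + f[qi]})
    return pd.DataFrame(rows)


def simulate_mas_values(n_above: int, n_below: int, threshold: float,
                        rng: np.random.Generator, margin: float = 0.03,
                        spread: float = 0.15) -> np.ndarray:
    """Per-subject MAS cumulative uptake values, strictly split at a threshold."""
    hi = threshold + margin + np.abs(rng.normal(spread, spread / 2, size=n_above))
    lo = threshold - margin - np.abs(rng.normal(spread, spread / 2, size=n_below))
    return np.concatenate([hi, np.clip(lo, 0.0, None)])


def simulate_group_values(group_means: dict[str, float], n_per_group: int,
                          sd: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-group uptake samples with designed means (e.g. surgical >
    non-surgical > control)."""
    return {g: rng.normal(m, sd, size=n_per_group) for g, m in group_means.items()}
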