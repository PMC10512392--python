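import numpy as np
import pandas as pd
import pytest

from synscreen.growth import GrowthCurve
from synscreen.hiphop import ScreenProfile, CombinationResult


@pytest.fixture
def logistic_curve():
    """Factory for exact logistic OD curves sampled every 15 minutes."""

    def _make(r=0.01, x0=0.01, k=1.0, n=96, dt=15.0, noise_sd=0.0, seed=0):
        t = np.arange(n) * dt
        od = k / (1.0 + ((k - x0) / x0) * np.exp(-r * t))
        if noise_sd > 0:
            od = od + np.random.default_rng(seed).normal(0, noise_sd, n)
        return GrowthCurve(times=t, ods=np.maximum(od, 0.0), well_id="w")

    return _make


def make_profile(treatment, z: dict, essentiality=None):
    strains = sorted(z)
    zs = pd.Series({s: float(z[s]) for s in strains})
    ess = pd.Series(
        {s: (essentiality or {}).get(s, "het-essential") for s in strains}
    )
    tags = pd.Series({s: "up" for s in strains})
    return ScreenProfile(treatment=treatment, z=zs, tag_used=tags, essentiality=ess)


@pytest.fixture
def combo_result():
    """Factory for a CombinationResult built from plain z dictionaries."""

    def _make(combo_z, *single_zs, essentiality=None):
        singles = list(single_zs)
        while len(singles) < 4:
            singles.append({s: 0.0 for s in combo_z})
        roles = ("a_ic20", "a_combo_dose", "b_ic20", "b_combo_dose")
        return CombinationResult(
            combo=make_profile("combo", combo_z, essentiality),
            **{
                role: make_profile(role, zs, essentiality)
                for role, zs in zip(roles, singles)
            },
        )

    return _make
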