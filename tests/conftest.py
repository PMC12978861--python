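import numpy as np
import pandas as pd
import pytest

from occdebt.data import DetectionHistory, StudyDataset


def make_dataset(y, subpopulation=None, habitat=None, drought=None,
                 discharge=None, developed=None, site_ids=None):
    """Build a valid StudyDataset around a detection array, filling covariate
    tables with benign defaults."""
    y = np.asarray(y, dtype=float)
    n, T, J = y.shape
    ids = site_ids or [f"S{i + 1:03d}" for i in range(n)]
    if habitat is None:
        habitat = np.full(n, 70.0)
    if developed is None:
        developed = np.full(n, 0.2)
    sites = pd.DataFrame({
        "subpopulation": subpopulation if subpopulation is not None else ["A"] * n,
        "huc10": ["0302020100"] * n,
        "drainage_area_km2": np.full(n, 400.0),
        "habitat_score": np.asarray(habitat, dtype=float),
        "substrate_score": np.full(n, 10.0),
        "cover_score": np.full(n, 12.0),
        "lulc_developed": np.asarray(developed, dtype=float),
        "lulc_herbpasture": np.full(n, 0.15),
        "lulc_crop": np.full(n, 0.1),
        "lulc_wetland": np.full(n, 0.05),
        "tqmean": np.full(n, 0.38),
    }, index=pd.Index(ids, name="site"))
    if drought is None:
        drought = np.zeros((n, T), dtype=int)
    det = DetectionHistory(ids, y)
    obs = det.observed
    if discharge is None:
        discharge = np.where(obs, 1.5, np.nan)
    bait = np.where(obs, np.minimum(np.arange(1, J + 1), 4)[None, None, :], np.nan).astype(float)
    return StudyDataset(det, sites, np.asarray(drought), np.asarray(discharge, dtype=float), bait)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def survey_design_dataset():
    """A 176-site, 5-season study mirroring the published survey bookkeeping:
    81 presence sites (70 of them with habitat score >= 60), and sites
    surveyed in exactly {1,2,3,4,5} seasons with counts {68,63,34,8,3}."""
    n, T, J = 176, 5, 4
    y = np.full((n, T, J), np.nan)
    counts = {1: 68, 2: 63, 3: 34, 4: 8, 5: 3}
    i = 0
    rs = np.random.default_rng(7)
    for k, c in counts.items():
        for _ in range(c):
            seasons = rs.choice(T, size=k, replace=False)
            y[i, seasons, :] = 0.0
            i += 1
    # first 81 sites get one detection in their first surveyed season
    for i in range(81):
        t = int(np.flatnonzero(~np.isnan(y[i]).all(axis=1))[0])
        y[i, t, 0] = 1.0
    habitat = np.full(n, 75.0)
    habitat[70:81] = 45.0      # 11 presence sites below the score threshold
    habitat[81:] = 55.0
    return make_dataset(y, habitat=habitat)
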