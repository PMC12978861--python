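"""Model specification and design-matrix construction.

Each of the four parameter groups (initial occupancy psi1, colonization gamma,
extinction epsilon, detection p) gets its own design matrix on the logit
scale. Covariates are referenced by name:

- site-level names are columns of ``dataset.sites`` (e.g. ``habitat_score``,
  ``lulc_developed``, ``tqmean``);
- ``drought`` is the season-level ordinal index, expanded to baseline-coded
  dummies ``drought_1..3`` with level 0 as baseline;
- ``discharge`` and ``bait_age`` are visit-level.

Continuous covariates are z-standardised (after a log transform where tagged)
using means/SDs over the rows that enter the likelihood: site-level columns
over sites, visit-level columns over performed visits. The applied scalings
are stored so rates can be predicted on new data on the same scale.

Interactions (``a:b`` between site-level covariates) are supported for psi1
only; the likelihood for the other groups routinely fails to converge with
interaction terms at realistic survey effort, so they are rejected there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import StudyDataset
from .errors import StudyValidationError

#: default transform per covariate name (anything else: "zscore")
DEFAULT_TRANSFORMS = {
    "discharge": "log_zscore",
    "bait_age": "zscore",
    "drought": "categorical",
}

_GROUPS = ("psi1", "gamma", "epsilon", "p")
_VISIT_LEVEL = {"discharge", "bait_age"}
_SEASON_LEVEL = {"drought"}


@dataclass
class ModelSpec:
    """Covariate structure of one candidate dynamic occupancy model.

    Each group lists covariate names (an intercept is always included).
    ``transforms`` overrides the per-name default transform tag, one of
    ``identity``, ``log``, ``zscore``, ``log_zscore``, ``categorical``.
    ``drought_alignment`` controls which season's drought index covaries with
    the transition t -> t+1: ``"next"`` (default) uses season t+1's index,
    ``"current"`` uses season t's.
    """

    psi1: tuple = ()
    gamma: tuple = ()
    epsilon: tuple = ()
    p: tuple = ()
    transforms: dict = field(default_factory=dict)
    drought_alignment: str = "next"
    name: str = "model"

    def __post_init__(self):
        self.psi1 = tuple(self.psi1)
        self.gamma = tuple(self.gamma)
        self.epsilon = tuple(self.epsilon)
        self.p = tuple(self.p)
        if self.drought_alignment not in ("next", "current"):
            raise ValueError(f"drought_alignment must be 'next' or 'current', got {self.drought_alignment!r}")
        for group in ("gamma", "epsilon", "p"):
            for term in getattr(self, group):
                if ":" in term:
                    raise StudyValidationError(
                        f"interaction term {term!r} not allowed for {group}; "
                        "interactions are supported for psi1 only"
                    )

    def group_terms(self, group: str) -> tuple:
        return getattr(self, group)

    def transform_of(self, name: str) -> str:
        return self.transforms.get(name, DEFAULT_TRANSFORMS.get(name, "zscore"))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**{k: v for k, v in d.items()})


@dataclass
class DesignMatrices:
    """Design matrices for the four groups plus stored scalings.

    Shapes: ``X_psi1`` (n, k1); ``X_gamma``/``X_epsilon`` (n, T-1, k);
    ``X_p`` (n, T, J, kp). ``scalings[name] = (mean, sd)`` for every
    z-standardised column, keyed by output column name.
    """

    X_psi1: np.ndarray
    X_gamma: np.ndarray
    X_epsilon: np.ndarray
    X_p: np.ndarray
    columns: dict           # group -> list of column names (incl. intercept)
    scalings: dict          # column name -> (mean, sd)

    @property
    def block_sizes(self) -> dict:
        return {g: len(self.columns[g]) for g in _GROUPS}

    @property
    def n_params(self) -> int:
        return sum(self.block_sizes.values())


def _site_column(dataset: StudyDataset, name: str) -> np.ndarray:
    if name not in dataset.sites.columns:
        raise StudyValidationError(f"unknown site covariate {name!r}")
    v = dataset.sites[name].to_numpy(dtype=float)
    if np.any(~np.isfinite(v)):
        i = int(np.argmax(~np.isfinite(v)))
        raise StudyValidationError(f"missing {name!r} for site {dataset.site_ids[i]!r}")
    return v


def _apply_transform(values: np.ndarray, name: str, transform: str,
                     mask: np.ndarray | None, scalings: dict) -> np.ndarray:
    """Transform + standardise one continuous column; record the scaling.

    ``mask`` selects the entries that enter the likelihood (None = all);
    mean/SD come from those entries only. A previously stored scaling (from
    fitting) is reused so prediction on new data stays on the training scale.
    """
    out = np.array(values, dtype=float)
    if transform in ("log", "log_zscore"):
        sel = out[mask] if mask is not None else out[np.isfinite(out)]
        if np.any(sel <= 0):
            raise StudyValidationError(f"{name!r}: log transform requires positive values")
        with np.errstate(invalid="ignore"):
            out = np.log(out)
    if transform in ("zscore", "log_zscore"):
        if name in scalings:
            mean, sd = scalings[name]
        else:
            sel = out[mask] if mask is not None else out[np.isfinite(out)]
            mean = float(np.mean(sel))
            sd = float(np.std(sel))
            if sd == 0.0:
                sd = 1.0  # constant column: centre only
            scalings[name] = (mean, sd)
        out = (out - mean) / sd
    return out


def build_design(spec: ModelSpec, dataset: StudyDataset,
                 scalings: dict | None = None) -> DesignMatrices:
    """Build design matrices for ``spec`` on ``dataset``.

    Pass ``scalings`` from a previous build to reuse training-scale
    standardisation (prediction / bootstrap refits on new detections reuse
    the covariates, so the scalings are identical anyway).
    """
    n, T, J = dataset.detections.y.shape
    scalings = dict(scalings) if scalings else {}
    obs = dataset.detections.observed

    site_cache: dict[str, np.ndarray] = {}

    def site_vec(name: str) -> np.ndarray:
        if name not in site_cache:
            raw = _site_column(dataset, name)
            site_cache[name] = _apply_transform(raw, name, spec.transform_of(name), None, scalings)
        return site_cache[name]

    def drought_dummies(t_index: np.ndarray) -> tuple[list[str], list[np.ndarray]]:
        # baseline-coded dummies for levels 1..3; level 0 is the baseline row
        d = dataset.drought[:, t_index]  # (n, len(t_index))
        names, cols = [], []
        for level in (1, 2, 3):
            names.append(f"drought_{level}")
            cols.append((d == level).astype(float))
        return names, cols

    columns: dict[str, list] = {}
    mats: dict[str, np.ndarray] = {}

    # ---- psi1 (site rows) ------------------------------------------------
    names = ["(intercept)"]
    cols = [np.ones(n)]
    for term in spec.psi1:
        if term in _SEASON_LEVEL or term in _VISIT_LEVEL:
            raise StudyValidationError(f"covariate {term!r} is not site-level; cannot enter psi1")
        if ":" in term:
            a, b = term.split(":", 1)
            cols.append(site_vec(a) * site_vec(b))
            names.append(f"{a}:{b}")
        else:
            cols.append(site_vec(term))
            names.append(term)
    mats["psi1"] = np.column_stack(cols)
    columns["psi1"] = names

    # ---- gamma / epsilon (site x transition rows) ------------------------
    trans_idx = np.arange(T - 1)
    if spec.drought_alignment == "next":
        drought_t = trans_idx + 1
    else:
        drought_t = trans_idx
    for group in ("gamma", "epsilon"):
        names = ["(intercept)"]
        cols = [np.ones((n, T - 1))]
        for term in spec.group_terms(group):
            if term == "drought":
                dnames, dcols = drought_dummies(drought_t)
                names.extend(dnames)
                cols.extend(dcols)
            elif term in _VISIT_LEVEL:
                raise StudyValidationError(f"covariate {term!r} is visit-level; cannot enter {group}")
            else:
                v = site_vec(term)
                cols.append(np.broadcast_to(v[:, None], (n, T - 1)).copy())
                names.append(term)
        mats[group] = np.stack(cols, axis=-1)
        columns[group] = names

    # ---- p (site x season x visit rows) ----------------------------------
    names = ["(intercept)"]
    cols = [np.ones((n, T, J))]
    for term in spec.p:
        if term == "drought":
            d = dataset.drought[:, :, None]  # broadcast over visits
            for level in (1, 2, 3):
                names.append(f"drought_{level}")
                cols.append(np.broadcast_to((d == level).astype(float), (n, T, J)).copy())
        elif term in _VISIT_LEVEL:
            raw = dataset.discharge if term == "discharge" else dataset.bait_age
            needed = obs & ~np.isfinite(raw)
            if needed.any():
                i, t, j = [int(v) for v in np.argwhere(needed)[0]]
                raise StudyValidationError(
                    f"missing {term!r} at observed visit: site {dataset.site_ids[i]!r}, "
                    f"season {t + 1}, visit {j + 1}"
                )
            x = _apply_transform(raw, term, spec.transform_of(term), obs, scalings)
            x = np.where(obs, x, 0.0)  # unused rows: any finite value
            names.append(term)
            cols.append(x)
        else:
            v = site_vec(term)
            cols.append(np.broadcast_to(v[:, None, None], (n, T, J)).copy())
            names.append(term)
    mats["p"] = np.stack(cols, axis=-1)
    columns["p"] = names

    return DesignMatrices(mats["psi1"], mats["gamma"], mats["epsilon"], mats["p"],
                          columns, scalings)
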