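"""Synthetic ocular-imaging cohorts with fellow-eye correlation.

Generates feature tables shaped like a small uveitis imaging study: three
groups (healthy controls, acute-phase and convalescent-phase disease),
one or two eyes per participant, 20 wide-field OCT-angiography metrics
plus two clinical covariates (logMAR best-corrected visual acuity and
intraocular pressure).  Features are Gaussian with group-dependent mean
shifts on a configurable informative subset and an equicorrelated
within-participant structure: fellow eyes share a participant-level
latent effect with weight sqrt(rho), so grouped cross-validation has a
real dependence structure to respect.

The generator emulates the statistical/grouping structure only — not the
physical units or marginal distributions of real OCTA metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OCTA_FEATURES",
    "CLINICAL_FEATURES",
    "ALL_FEATURES",
    "GroupSpec",
    "CohortSpec",
    "FeatureTable",
    "Standardizer",
    "default_cohort_spec",
    "generate",
    "make_datasets",
    "standardize",
]

# 2 FAZ metrics, 7 perfusion densities, 5 length densities, 6 flow-void
# metrics: the 20-feature wide-field OCTA roster.
OCTA_FEATURES: tuple = (
    "AFAZ",
    "AI",
    "macular_SVP_VPD",
    "macular_DVP_VPD",
    "macular_CC_VPD",
    "peripapillary_SVP_VPD",
    "whole_FOV_SVP_VPD",
    "whole_FOV_DVP_VPD",
    "whole_FOV_CC_VPD",
    "macular_SVP_VLD",
    "macular_DVP_VLD",
    "peripapillary_SVP_VLD",
    "whole_FOV_SVP_VLD",
    "whole_FOV_DVP_VLD",
    "macular_CC_FVAR",
    "macular_CC_FV1000",
    "macular_CC_FVAS",
    "peripheral_CC_FVAR",
    "peripheral_CC_FV1000",
    "peripheral_CC_FVAS",
)
CLINICAL_FEATURES: tuple = ("logMAR_BCVA", "IOP")
ALL_FEATURES: tuple = OCTA_FEATURES + CLINICAL_FEATURES

ID_COLUMNS = ("eye_id", "participant_id", "group")


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group: participant count and total eye count."""

    name: str
    n_participants: int
    n_eyes: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_eyes <= 2 * self.n_participants:
            raise ValueError(
                f"group {self.name!r}: n_eyes must lie in [1, 2*n_participants], "
                f"got {self.n_eyes} eyes for {self.n_participants} participants"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a synthetic cohort.

    ``effect_matrix`` holds per-feature, per-group mean shifts in units of
    the eye-level standard deviation (rows = features, columns = groups).
    ``within_participant_correlation`` (rho) is the correlation between
    fellow eyes of one participant; ``noise_sd`` scales every feature.
    """

    groups: tuple
    feature_names: tuple = ALL_FEATURES
    effect_matrix: pd.DataFrame | None = None
    within_participant_correlation: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not 0.0 <= self.within_participant_correlation < 1.0:
            raise ValueError("within_participant_correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        effects = self.effect_matrix
        if effects is None:
            effects = pd.DataFrame(
                0.0,
                index=list(self.feature_names),
                columns=[g.name for g in self.groups],
            )
        else:
            effects = pd.DataFrame(effects).astype(float)
            if list(effects.index) != list(self.feature_names):
                raise ValueError("effect_matrix rows must match feature_names in order")
            if list(effects.columns) != [g.name for g in self.groups]:
                raise ValueError("effect_matrix columns must match group names in order")
        object.__setattr__(self, "effect_matrix", effects)
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    def to_dict(self) -> dict:
        return {
            "groups": [
                {"name": g.name, "n_participants": g.n_participants, "n_eyes": g.n_eyes}
                for g in self.groups
            ],
            "feature_names": list(self.feature_names),
            "effect_matrix": {
                g: self.effect_matrix[g].tolist() for g in self.effect_matrix.columns
            },
            "within_participant_correlation": self.within_participant_correlation,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        groups = tuple(GroupSpec(**g) for g in d["groups"])
        names = tuple(d.get("feature_names", ALL_FEATURES))
        effects = d.get("effect_matrix")
        if effects is not None:
            effects = pd.DataFrame(
                {g.name: effects[g.name] for g in groups}, index=list(names)
            )
        return cls(
            groups=groups,
            feature_names=names,
            effect_matrix=effects,
            within_participant_correlation=d.get("within_participant_correlation", 0.5),
            noise_sd=d.get("noise_sd", 1.0),
            seed=d.get("seed", 0),
        )


# Default study-shaped conditions: 30/20/30 eyes from 15/13/17 participants.
# Three informative features at 2-SD shifts: a choriocapillaris perfusion
# deficit persisting through both disease phases, plus two phase-specific
# markers moving in opposite directions between acute inflammation and
# convalescent remodelling, so all three classes are mutually separable.
DEFAULT_INFORMATIVE_EFFECTS = {
    "whole_FOV_CC_VPD": {"HC": 0.0, "acute": -2.0, "convalescent": -2.0},
    "macular_DVP_VLD": {"HC": 0.0, "acute": 2.0, "convalescent": -2.0},
    "AFAZ": {"HC": 0.0, "acute": -2.0, "convalescent": 2.0},
}


def default_cohort_spec(
    effect_scale: float = 1.0,
    within_participant_correlation: float = 0.5,
    seed: int = 0,
) -> CohortSpec:
    """The study-shaped cohort: 80 eyes, 22 features, 3 informative markers.

    ``effect_scale`` multiplies the default 2-SD informative shifts;
    ``effect_scale=0`` gives a null cohort with no group differences.
    """
    groups = (
        GroupSpec("HC", 15, 30),
        GroupSpec("acute", 13, 20),
        GroupSpec("convalescent", 17, 30),
    )
    effects = pd.DataFrame(
        0.0, index=list(ALL_FEATURES), columns=[g.name for g in groups]
    )
    for feat, shifts in DEFAULT_INFORMATIVE_EFFECTS.items():
        for grp, val in shifts.items():
            effects.loc[feat, grp] = val * effect_scale
    return CohortSpec(
        groups=groups,
        feature_names=ALL_FEATURES,
        effect_matrix=effects,
        within_participant_correlation=within_participant_correlation,
        seed=seed,
    )


@dataclass
class FeatureTable:
    """Eyes-by-features table with participant grouping and class labels.

    Backed by a DataFrame whose first three columns are ``eye_id``,
    ``participant_id`` and ``group``, followed by numeric feature columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table lacks required columns {missing}")
        feats = self.data[list(self.feature_names)]
        if feats.isna().any().any():
            raise ValueError("feature table contains missing values")
        span = self.data.groupby("participant_id")["group"].nunique()
        if (span > 1).any():
            bad = span[span > 1].index.tolist()
            raise ValueError(f"participants assigned to multiple groups: {bad}")

    @property
    def feature_names(self) -> list:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def y(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    @property
    def participant_ids(self) -> np.ndarray:
        return self.data["participant_id"].to_numpy()

    @property
    def eye_ids(self) -> np.ndarray:
        return self.data["eye_id"].to_numpy()

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    @property
    def n_eyes(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path))


def generate(spec: CohortSpec, rng: np.random.Generator | None = None) -> FeatureTable:
    """Sample a cohort from the spec.

    Each participant draws a latent vector shared by their eyes; each eye's
    feature value is ``noise_sd * (shift + sqrt(rho)*latent + sqrt(1-rho)*noise)``
    so the marginal SD is ``noise_sd`` and fellow eyes correlate at rho.
    Which participants contribute one vs two eyes is randomised within each
    group's eye budget.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rho = spec.within_participant_correlation
    n_feat = len(spec.feature_names)
    rows = []
    pid_counter = 0
    eye_counter = 0
    for group in spec.groups:
        shift = spec.effect_matrix[group.name].to_numpy()
        n_bilateral = group.n_eyes - group.n_participants
        bilateral = np.zeros(group.n_participants, dtype=bool)
        bilateral[rng.permutation(group.n_participants)[:n_bilateral]] = True
        for p in range(group.n_participants):
            pid = f"P{pid_counter:03d}"
            pid_counter += 1
            latent = rng.standard_normal(n_feat)
            for _ in range(2 if bilateral[p] else 1):
                noise = rng.standard_normal(n_feat)
                values = spec.noise_sd * (
                    shift + np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * noise
                )
                rows.append(
                    {"eye_id": f"E{eye_counter:03d}", "participant_id": pid, "group": group.name}
                    | dict(zip(spec.feature_names, values))
                )
                eye_counter += 1
    return FeatureTable(pd.DataFrame(rows))


def make_datasets(table: FeatureTable) -> dict:
    """The four analysis views of one cohort.

    1: imaging features only, disease phases merged into one class;
    2: all features, merged classes; 3: imaging features, three classes;
    4: all features, three classes.  Row counts are identical across views.
    """
    clinical = [c for c in CLINICAL_FEATURES if c in table.feature_names]

    def _view(drop_clinical: bool, merge: bool) -> FeatureTable:
        df = table.data.copy()
        if drop_clinical:
            df = df.drop(columns=clinical)
        if merge:
            df["group"] = df["group"].map(
                lambda g: "VKH" if g in ("acute", "convalescent") else g
            )
        return FeatureTable(df)

    return {
        1: _view(True, True),
        2: _view(False, True),
        3: _view(True, False),
        4: _view(False, False),
    }


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-score parameters, reusable on held-out data."""

    means: pd.Series
    sds: pd.Series

    def transform(self, table: FeatureTable) -> FeatureTable:
        df = table.data.copy()
        names = table.feature_names
        if list(names) != list(self.means.index):
            raise ValueError("feature columns do not match the fitted standardizer")
        df[names] = (df[names] - self.means) / self.sds
        return FeatureTable(df)


def standardize(table: FeatureTable) -> tuple[FeatureTable, Standardizer]:
    """Z-score every feature column (population SD); store the parameters.

    Raises naming the offending column when a feature has zero variance.
    """
    feats = table.features
    means = feats.mean()
    sds = feats.std(ddof=0)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance feature columns cannot be standardized: {zero}")
    scaler = Standardizer(means=means, sds=sds)
    return scaler.transform(table), scaler
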