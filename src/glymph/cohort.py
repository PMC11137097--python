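"""Synthetic CN/AD cohort tables with a prescribed correlation structure.

The generator treats amyloid burden (centiloid) as the exogenous stage
axis: each subject's centiloid is drawn from their group's normal
distribution, the ALPS indexes are generated from centiloid through the
configured linear links, and MMSE and the VSRAD atrophy Z-score are in
turn generated from ALPS(b=1000) through their links.  Residual standard
deviations are solved from the requested pooled Pearson correlations, so a
large simulated cohort recovers the configured slopes, intercepts and r —
the structure group-comparison and regression analyses are meant to detect.

For a link with ALPS as response (slope b, correlation r) the implied
predictor SD is ``sigma_x = r * sigma_alps / b``; "inverting" the link
generates the predictor as

    x = mu_x + (r^2 / b) * (ALPS - mu_alps) + N(0, sigma_x * sqrt(1 - r^2)),

which reproduces both the printed response-orientation slope and r when
the generated table is re-analysed.  MMSE is clipped to [0, 30] and
rounded to integers after generation (real MMSE is a bounded integer
score); heavy clipping is reported as a warning because it attenuates the
achievable correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "GroupParams",
    "LinkSpec",
    "CohortSpec",
    "simulate_cohort",
    "clipped_normal_mean",
]

#: warn if more than this fraction of MMSE draws hit the [0, 30] bounds
MMSE_CLIP_WARN_FRACTION = 0.25


@dataclass(frozen=True)
class GroupParams:
    """Size and marginal moments of one diagnostic group."""

    n: int
    n_male: int
    age_mean: float
    age_sd: float
    centiloid_mean: float
    centiloid_sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if not 0 <= self.n_male <= self.n:
            raise ValueError("n_male out of range")
        if self.age_sd <= 0 or self.centiloid_sd <= 0:
            raise ValueError("group SDs must be positive")


@dataclass(frozen=True)
class LinkSpec:
    """A linear link y = intercept + slope * x with pooled Pearson r."""

    slope: float
    intercept: float
    r: float

    def __post_init__(self):
        if not 0 < abs(self.r) < 1:
            raise ValueError(f"|r| must be in (0, 1), got {self.r}")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


@dataclass(frozen=True)
class CohortSpec:
    """Full generative specification of a two-group biomarker cohort."""

    cn: GroupParams
    ad: GroupParams
    alps_links: dict[str, LinkSpec] = field(default_factory=dict)
    mmse_link: LinkSpec | None = None
    vsrad_link: LinkSpec | None = None

    def __post_init__(self):
        if "b1000" not in self.alps_links:
            raise ValueError("alps_links must define at least the b1000 shell")

    # -- analytic moments implied by the generative model ------------------

    @property
    def n_total(self) -> int:
        return self.cn.n + self.ad.n

    def centiloid_pooled_moments(self) -> tuple[float, float]:
        """Mean and SD of the two-group centiloid mixture."""
        w = np.array([self.cn.n, self.ad.n], dtype=float) / self.n_total
        mu = np.array([self.cn.centiloid_mean, self.ad.centiloid_mean])
        sd = np.array([self.cn.centiloid_sd, self.ad.centiloid_sd])
        m = float(w @ mu)
        var = float(w @ (sd**2 + (mu - m) ** 2))
        return m, np.sqrt(var)

    def alps_residual_sd(self, shell: str) -> float:
        """sigma_res = |slope| * SD(pooled centiloid) * sqrt(1/r^2 - 1)."""
        link = self.alps_links[shell]
        _, sd = self.centiloid_pooled_moments()
        return abs(link.slope) * sd * np.sqrt(1.0 / link.r**2 - 1.0)

    def alps_pooled_moments(self, shell: str) -> tuple[float, float]:
        link = self.alps_links[shell]
        m, sd = self.centiloid_pooled_moments()
        mu = link.intercept + link.slope * m
        total_sd = abs(link.slope) * sd / abs(link.r)
        return mu, total_sd

    def alps_group_moments(self, shell: str, group: str) -> tuple[float, float]:
        link = self.alps_links[shell]
        g = self.cn if group == "CN" else self.ad
        mu = link.intercept + link.slope * g.centiloid_mean
        sd = np.hypot(link.slope * g.centiloid_sd, self.alps_residual_sd(shell))
        return mu, float(sd)

    def _mmse_coefficients(self) -> tuple[float, float, float]:
        """(mu_pool, slope on ALPS, residual SD) of the pre-clip MMSE."""
        link = self.mmse_link
        mu_a, sd_a = self.alps_pooled_moments("b1000")
        sigma_m = link.r * sd_a / link.slope
        if sigma_m <= 0:
            raise ValueError(
                "mmse_link slope and r must share a sign (implied SD <= 0)"
            )
        mu_m = (mu_a - link.intercept) / link.slope
        return mu_m, link.r**2 / link.slope, sigma_m * np.sqrt(1.0 - link.r**2)

    def _vsrad_residual_sd(self) -> float:
        link = self.vsrad_link
        _, sd_a = self.alps_pooled_moments("b1000")
        sigma_v = abs(link.slope) * sd_a / abs(link.r)
        return sigma_v * np.sqrt(1.0 - link.r**2)

    def expected_group_mean(self, column: str, group: str) -> float:
        """Analytic expectation of a per-group sample mean under the generator.

        Accounts for the [0, 30] clipping of MMSE via the censored-normal
        mean (rounding is treated as unbiased).
        """
        g = self.cn if group == "CN" else self.ad
        if column == "centiloid":
            return g.centiloid_mean
        if column == "age":
            return g.age_mean
        if column.startswith("alps_"):
            return self.alps_group_moments(column.removeprefix("alps_"), group)[0]
        mu_a, sd_a = self.alps_group_moments("b1000", group)
        if column == "vsrad_z":
            link = self.vsrad_link
            return link.intercept + link.slope * mu_a
        if column == "mmse":
            mu_m, c1, res_sd = self._mmse_coefficients()
            mu_pool_a = self.alps_pooled_moments("b1000")[0]
            mu = mu_m + c1 * (mu_a - mu_pool_a)
            sd = np.hypot(c1 * sd_a, res_sd)
            return clipped_normal_mean(mu, sd, 0.0, 30.0)
        raise KeyError(column)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict) -> "CohortSpec":
        groups = cfg["groups"]
        return cls(
            cn=GroupParams(**groups["CN"]),
            ad=GroupParams(**groups["AD"]),
            alps_links={k: LinkSpec(**v) for k, v in cfg["alps_links"].items()},
            mmse_link=LinkSpec(**cfg["mmse_link"]) if cfg.get("mmse_link") else None,
            vsrad_link=LinkSpec(**cfg["vsrad_link"]) if cfg.get("vsrad_link") else None,
        )

    @classmethod
    def study_defaults(cls) -> "CohortSpec":
        """The shipped default conditions (27 CN + 56 AD)."""
        text = resources.files("glymph.data").joinpath("study_defaults.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


def clipped_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """E[min(max(X, lo), hi)] for X ~ N(mu, sd): censored-normal mean."""
    a, b = (lo - mu) / sd, (hi - mu) / sd
    Phi, phi = stats.norm.cdf, stats.norm.pdf
    return float(
        lo * Phi(a) + hi * (1 - Phi(b))
        + mu * (Phi(b) - Phi(a)) - sd * (phi(b) - phi(a))
    )


def simulate_cohort(spec: CohortSpec | None = None,
                    rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Draw one cohort table.

    Columns: subject_id, group, age, sex, mmse, vsrad_z, centiloid,
    alps_b1000, alps_b2000 (ALPS columns only for configured shells).
    Identical spec and seed give a bit-identical table.
    """
    if spec is None:
        spec = CohortSpec.study_defaults()
    rng = np.random.default_rng(rng)

    frames = []
    for name, g in (("CN", spec.cn), ("AD", spec.ad)):
        sex = np.array(["M"] * g.n_male + ["F"] * (g.n - g.n_male))
        rng.shuffle(sex)
        frames.append(pd.DataFrame({
            "subject_id": [f"{name}{i + 1:03d}" for i in range(g.n)],
            "group": name,
            "age": np.round(rng.normal(g.age_mean, g.age_sd, g.n), 1),
            "sex": sex,
            "centiloid": rng.normal(g.centiloid_mean, g.centiloid_sd, g.n),
        }))
    df = pd.concat(frames, ignore_index=True)

    for shell, link in spec.alps_links.items():
        res = spec.alps_residual_sd(shell)
        df[f"alps_{shell}"] = (link.intercept + link.slope * df["centiloid"]
                               + rng.normal(0.0, res, len(df)))

    alps = df["alps_b1000"].to_numpy()
    mu_pool_a = spec.alps_pooled_moments("b1000")[0]

    if spec.mmse_link is not None:
        mu_m, c1, res_sd = spec._mmse_coefficients()
        raw = mu_m + c1 * (alps - mu_pool_a) + rng.normal(0.0, res_sd, len(df))
        clipped = np.clip(raw, 0.0, 30.0)
        frac = float(np.mean(clipped != raw))
        if frac > MMSE_CLIP_WARN_FRACTION:
            warnings.warn(
                f"{frac:.0%} of MMSE draws hit the [0, 30] bounds; the "
                f"requested MMSE correlation r={spec.mmse_link.r} is not "
                "achievable with this much clipping", stacklevel=2)
        df["mmse"] = np.round(clipped).astype(int)

    if spec.vsrad_link is not None:
        link = spec.vsrad_link
        df["vsrad_z"] = (link.intercept + link.slope * alps
                         + rng.normal(0.0, spec._vsrad_residual_sd(), len(df)))

    cols = ["subject_id", "group", "age", "sex", "mmse", "vsrad_z", "centiloid"]
    cols = [c for c in cols if c in df] + [c for c in df if c.startswith("alps_")]
    return df[cols]
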