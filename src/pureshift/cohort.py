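"""Cohort concentration simulation.

Concentrations are drawn log-normally: positivity is guaranteed and the
coefficient of variation and inter-metabolite correlation act on the log
scale (a multiplicative error model, the natural one for extraction yield
variation).  Intramolecular covariance needs no modelling at all — every
proton group of a metabolite scales with the one concentration drawn for
it, which is exactly the collinearity STOCSY exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: Concentration range (mM) spanned by the quantified extract constituents.
CONC_RANGE = (0.5, 110.0)


@dataclass
class CohortDesign:
    """Study design: groups, replicate counts and the generative model.

    Parameters
    ----------
    groups : list of str
        Group (growing-region) names.
    replicates : dict
        Group name -> replicate count.
    mean_mM : dict
        Metabolite -> cohort-mean concentration in mM, inside ``CONC_RANGE``.
    cv : float or dict
        Coefficient of variation of concentration (shared scalar or per
        metabolite).  CV = 0 collapses the draw onto the group means.
    group_multipliers : dict
        Group -> {metabolite -> multiplier} applied to the mean; unspecified
        entries default to 1.  These offsets are what drives PLS-DA class
        separation.
    correlation_blocks : list of (list of metabolites, rho)
        Pairwise correlation of log-concentrations inside each block.
        Blocks are applied in order and later blocks override earlier pair
        entries, so a mixed-sign structure (e.g. sugars mutually positive,
        each anti-correlated with sucrose) is expressed by listing the
        anti-correlation block first and the tighter positive block second.
    """

    groups: list[str]
    replicates: dict[str, int]
    mean_mM: dict[str, float]
    cv: float | dict[str, float] = 0.2
    group_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    correlation_blocks: list[tuple[list[str], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = CONC_RANGE
        for met, mu in self.mean_mM.items():
            if not (lo <= mu <= hi):
                raise ValueError(f"{met}: mean {mu} mM outside [{lo}, {hi}] mM")
        for met, c in self._cv_map().items():
            if c < 0:
                raise ValueError(f"{met}: negative CV {c}")
        for g in self.groups:
            if self.replicates.get(g, 0) < 1:
                raise ValueError(f"group {g!r}: missing or non-positive replicate count")
        for names, rho in self.correlation_blocks:
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"block correlation {rho} outside [-1, 1]")
            unknown = set(names) - set(self.mean_mM)
            if unknown:
                raise ValueError(f"correlation block references unknown metabolites {sorted(unknown)}")
        r = self.correlation_matrix()
        w = np.linalg.eigvalsh(r)
        if w.min() < -1e-8:
            raise ValueError(f"assembled correlation matrix is not positive semi-definite (min eigenvalue {w.min():.3g})")

    @property
    def metabolites(self) -> list[str]:
        return list(self.mean_mM)

    @property
    def n_samples(self) -> int:
        return sum(self.replicates[g] for g in self.groups)

    def _cv_map(self) -> dict[str, float]:
        if isinstance(self.cv, dict):
            return {m: float(self.cv.get(m, 0.0)) for m in self.mean_mM}
        return {m: float(self.cv) for m in self.mean_mM}

    def correlation_matrix(self) -> np.ndarray:
        """Assemble the log-scale correlation matrix from the blocks."""
        mets = self.metabolites
        idx = {m: i for i, m in enumerate(mets)}
        r = np.eye(len(mets))
        for names, rho in self.correlation_blocks:
            for a in names:
                for b in names:
                    if a != b:
                        r[idx[a], idx[b]] = rho
        return r


@dataclass
class ConcentrationTable:
    """Per-sample metabolite concentrations (mM) with group labels."""

    data: pd.DataFrame  # index = sample ids, columns = metabolites
    groups: pd.Series  # index = sample ids, values = group names

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            raise ValueError("concentration rows and group labels are misaligned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    def sample(self, sample_id: str) -> dict[str, float]:
        return self.data.loc[sample_id].to_dict()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        out.insert(0, "sample", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationTable":
        df = pd.read_csv(path)
        df = df.set_index("sample")
        groups = df.pop("group")
        return cls(df, groups)


def simulate_concentrations(design: CohortDesign, seed: int) -> ConcentrationTable:
    """Draw a cohort concentration table from the design's generative model.

    Log-concentrations are multivariate normal with per-metabolite sigma
    sqrt(log(1 + CV²)), mean log(group mean · multiplier) − sigma²/2 (so the
    arithmetic mean equals the design mean) and the block-assembled
    correlation.  Draws are clipped to ``CONC_RANGE`` (truncation, not
    resampling) and fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    mets = design.metabolites
    cvm = design._cv_map()
    sigma = np.array([np.sqrt(np.log1p(cvm[m] ** 2)) for m in mets])
    corr = design.correlation_matrix()
    cov = corr * np.outer(sigma, sigma)
    # eigh-based factor: tolerant of semi-definite block structures
    w, v = np.linalg.eigh(cov)
    factor = v * np.sqrt(np.clip(w, 0.0, None))

    rows, ids, labels = [], [], []
    for g in design.groups:
        mult = design.group_multipliers.get(g, {})
        mean = np.array([design.mean_mM[m] * mult.get(m, 1.0) for m in mets])
        mu = np.log(mean) - sigma**2 / 2.0
        n = design.replicates[g]
        z = rng.standard_normal((n, len(mets)))
        logc = mu + z @ factor.T
        rows.append(np.exp(logc))
        ids.extend(f"{g}-{i + 1:02d}" for i in range(n))
        labels.extend([g] * n)
    conc = np.clip(np.vstack(rows), *CONC_RANGE)
    df = pd.DataFrame(conc, index=pd.Index(ids, name="sample"), columns=mets)
    return ConcentrationTable(df, pd.Series(labels, index=df.index, name="group"))


def default_design() -> CohortDesign:
    """Six-region Cape-gooseberry cohort: n = 10 per region, 7 for Celendin III.

    Means sit inside the 0.5–110 mM span of the quantified constituents;
    the sugar block carries the pathway structure seen in the real fruit
    (glucose/fructose anomers mutually correlated, all anti-correlated with
    sucrose, consistent with invertase-driven interconversion) and the group
    multipliers plant the modest regional composition offsets the
    discriminant analysis is meant to pick up.
    """
    sugars = ["alpha-glucose", "beta-glucose", "beta-fructose"]
    return CohortDesign(
        groups=["San Marcos", "Celendin I", "Celendin II", "Celendin III",
                "Bambamarca I", "Bambamarca II"],
        replicates={"San Marcos": 10, "Celendin I": 10, "Celendin II": 10,
                    "Celendin III": 7, "Bambamarca I": 10, "Bambamarca II": 10},
        mean_mM={
            "sucrose": 60.0,
            "alpha-glucose": 20.0,
            "beta-glucose": 30.0,
            "beta-fructose": 35.0,
            "proline": 8.0,
            "glutamic acid": 3.0,
            "glutamine": 4.0,
            "GABA": 2.5,
            "malic acid": 15.0,
            "asparagine": 5.0,
            "myo-inositol": 6.0,
            "citric acid": 10.0,
            "alanine": 2.0,
        },
        cv=0.2,
        group_multipliers={
            "San Marcos": {"sucrose": 1.30, "alpha-glucose": 0.80,
                           "beta-glucose": 0.80, "beta-fructose": 0.80},
            "Celendin I": {"sucrose": 0.75, "alpha-glucose": 1.25,
                           "beta-glucose": 1.25, "beta-fructose": 1.25},
            "Celendin II": {"malic acid": 1.40, "citric acid": 1.30},
            "Celendin III": {"proline": 1.50, "GABA": 1.40},
            "Bambamarca I": {},
            "Bambamarca II": {"glutamic acid": 1.40, "glutamine": 1.30, "alanine": 1.30},
        },
        correlation_blocks=[
            (["sucrose"] + sugars, -0.8),
            (sugars, 0.9),
        ],
    )


# ---------------------------------------------------------------------------
# YAML round-trip


def design_to_dict(d: CohortDesign) -> dict:
    return {
        "groups": list(d.groups),
        "replicates": dict(d.replicates),
        "mean_mM": dict(d.mean_mM),
        "cv": d.cv if not isinstance(d.cv, dict) else dict(d.cv),
        "group_multipliers": {g: dict(m) for g, m in d.group_multipliers.items()},
        "correlation_blocks": [{"metabolites": list(n), "rho": float(r)}
                               for n, r in d.correlation_blocks],
    }


def design_from_dict(d: dict) -> CohortDesign:
    return CohortDesign(
        groups=list(d["groups"]),
        replicates={k: int(v) for k, v in d["replicates"].items()},
        mean_mM={k: float(v) for k, v in d["mean_mM"].items()},
        cv=d.get("cv", 0.2),
        group_multipliers=d.get("group_multipliers", {}),
        correlation_blocks=[(list(b["metabolites"]), float(b["rho"]))
                            for b in d.get("correlation_blocks", [])],
    )


def save_design(d: CohortDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(d), fh, sort_keys=False)


def load_design(path) -> CohortDesign:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))
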