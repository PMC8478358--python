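"""Seeded generators for trees, allometric traits and specimen tables.

The generators reproduce the statistical structure the analysis assumes so
every stage is testable without the original compilations: an ultrametric
pure-birth (Yule) tree; two log-scale traits linearly related with
phylogenetically structured residuals (Brownian motion with Pagel's
lambda); and specimen-level replicates with adult/subadult flags plus
fossil-style records carrying OCW, endocranial volume and age.

Defaults mirror the extant-cetacean OCW compilation the body-mass
calibration rests on: 35 species, about 105 specimens of which roughly
two-thirds are adults, specimen-level coefficient of variation 0.10, and
the OCW power law (slope 3.135, intercept -3.575) with lambda 0.942.
Every entry point takes a mandatory seed; there is no unseeded randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .phylo import PhyloTree, parse_newick

__all__ = [
    "SimulationSpec",
    "simulate_yule_tree",
    "simulate_allometric_traits",
    "simulate_specimen_table",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Study-shaped simulation conditions.

    Attributes
    ----------
    n_tips
        Species count (tree tips).
    birth_rate
        Speciation rate of the pure-birth tree (events per unit time).
    slope, intercept
        True log10-log10 relation between predictor and response.
    sigma2
        Residual variance of the response on the log10 scale.
    lam
        Pagel's lambda structuring the residuals.
    x_root, x_sigma2
        Root state and Brownian rate of the log10 predictor.
    replicates
        Specimens measured per species.
    cv
        Specimen-level coefficient of variation (lognormal, natural scale).
    subadult_fraction
        Probability a specimen is flagged subadult.
    subadult_shrink
        Multiplicative body-size factor for subadult specimens (< 1).
    n_fossils
        Fossil-style records (OCW + endocranial volume + age) to emit.
    seed
        Mandatory random seed.
    """

    n_tips: int = 35
    birth_rate: float = 1.0
    slope: float = 3.135
    intercept: float = -3.575
    sigma2: float = 0.08
    lam: float = 0.942
    x_root: float = 2.0
    x_sigma2: float = 0.12
    replicates: int = 3
    cv: float = 0.10
    subadult_fraction: float = 0.34
    subadult_shrink: float = 0.7
    n_fossils: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        for name in ("sigma2", "x_sigma2", "cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.subadult_fraction <= 1.0):
            raise ValueError("subadult_fraction must lie in [0, 1]")

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=seed)


def _rng(spec: SimulationSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _yule_newick(spec: SimulationSpec, rng: np.random.Generator) -> str:
    """Grow a pure-birth tree forward in time and serialise it to Newick."""
    n, rate = spec.n_tips, spec.birth_rate
    start: dict[int, float] = {1: 0.0, 2: 0.0}
    children: dict[int, list[int]] = {0: [1, 2]}  # 0 is the root
    active = [1, 2]
    next_id = 3
    t = 0.0
    for k in range(2, n + 1):
        t += rng.exponential(1.0 / (k * rate))
        if k == n:
            break  # final Exp(n*rate) wait just elapsed; stop at the present
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        a, b = next_id, next_id + 1
        next_id += 2
        children[node] = [a, b]
        start[a] = start[b] = t
        active.extend([a, b])
    t_end = t

    tip_counter = [1]

    def newick(node: int) -> str:
        kids = children.get(node)
        if kids is not None:
            end = start[kids[0]]
            inner = ",".join(newick(c) for c in kids)
            return f"({inner}):{end - start[node]:.12g}"
        lab = f"sp{tip_counter[0]:03d}"
        tip_counter[0] += 1
        return f"{lab}:{t_end - start[node]:.12g}"

    inner = ",".join(newick(c) for c in children[0])
    return f"({inner}):0;"


def simulate_yule_tree(spec: SimulationSpec,
                       rng: np.random.Generator | None = None) -> PhyloTree:
    """Ultrametric pure-birth tree with ``spec.n_tips`` tips.

    Starting from two lineages at the root, with k extant lineages the wait
    to the next split is Exp(k * birth_rate) and a uniformly chosen lineage
    splits; after the n-th lineage appears one final Exp(n * birth_rate)
    wait elapses before the present, so the expected depth is
    sum_{k=2..n} 1/(k * birth_rate).  Deterministic given the seed.
    """
    rng = _rng(spec) if rng is None else rng
    return parse_newick(_yule_newick(spec, rng))


def simulate_allometric_traits(
    tree: PhyloTree,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Species-level trait table (taxon, x, y) on the natural scale.

    log10 x evolves by Brownian motion on the tree (rate ``x_sigma2`` from
    root state ``x_root``); log10 y = slope * log10 x + intercept plus a
    multivariate-normal residual with covariance sigma2 * V(lambda).
    """
    rng = _rng(spec) if rng is None else rng
    cov1 = tree.covariance(1.0)
    taxa = list(cov1.taxa)
    n = len(taxa)
    # normalise to unit mean depth so x_sigma2 and sigma2 are tip-level
    # variances regardless of the tree's time scale
    base = cov1.matrix / float(np.mean(np.diag(cov1.matrix)))
    jitter = 1e-12 * np.eye(n)  # guards exact ties in ultrametric covariances
    L1 = np.linalg.cholesky(base + jitter)
    x = spec.x_root + np.sqrt(spec.x_sigma2) * (L1 @ rng.standard_normal(n))
    Vlam = base * spec.lam
    np.fill_diagonal(Vlam, np.diag(base))
    if spec.sigma2 > 0:
        Llam = np.linalg.cholesky(Vlam + jitter)
        resid = np.sqrt(spec.sigma2) * (Llam @ rng.standard_normal(n))
    else:
        resid = np.zeros(n)
    y = spec.slope * x + spec.intercept + resid
    return pd.DataFrame({"taxon": taxa, "x": 10.0 ** x, "y": 10.0 ** y})


def simulate_specimen_table(
    tree: PhyloTree,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Specimen-level records emulating the extant OCW/body-mass compilation.

    Species true values come from :func:`simulate_allometric_traits`
    (x = OCW in mm, y = body mass in kg).  Each species contributes
    ``replicates`` specimens whose values are the species values perturbed
    by mean-one lognormal noise at coefficient of variation ``cv``;
    specimens flagged subadult (probability ``subadult_fraction``) have
    their body mass shrunk by ``subadult_shrink`` (and OCW by its cube
    root, since a linear dimension scales as mass^(1/3)) so maturity
    filters have something to remove.  Optionally appends ``n_fossils``
    fossil-style records carrying OCW, endocranial volume and an
    Eocene-like age instead of direct measurements.
    """
    rng = _rng(spec) if rng is None else rng
    species = simulate_allometric_traits(tree, spec, rng)
    log_sd = float(np.sqrt(np.log1p(spec.cv**2)))
    rows = []
    for _, sp in species.iterrows():
        for rep in range(spec.replicates):
            subadult = bool(rng.random() < spec.subadult_fraction)
            factor = spec.subadult_shrink if subadult else 1.0
            noise_x = float(np.exp(log_sd * rng.standard_normal() - 0.5 * log_sd**2))
            noise_y = float(np.exp(log_sd * rng.standard_normal() - 0.5 * log_sd**2))
            rows.append({
                "taxon": sp["taxon"],
                "specimen_id": f"{sp['taxon']}-{rep + 1}",
                "group": "cetacean",
                "maturity": "subadult" if subadult else "adult",
                "ocw_mm": sp["x"] * factor ** (1.0 / 3.0) * noise_x,
                "body_mass_kg": sp["y"] * factor * noise_y,
                "age_ma": 0.0,
            })
    for i in range(spec.n_fossils):
        # OCW around the extant midrange; endocranial volume consistent with
        # an EQ-near-1 brain plus an adnexa/CSF allowance; Eocene-like age
        ocw = float(np.exp(rng.normal(np.log(100.0), 0.25)))
        body_kg = 10.0 ** (spec.slope * np.log10(ocw) + spec.intercept)
        brain_g = 10.0 ** (0.56 * np.log10(body_kg * 1000.0) - 0.44)
        endo = float(brain_g / 1.04 * np.exp(rng.normal(0.25, 0.1)))
        rows.append({
            "taxon": f"fossil{i + 1:02d}",
            "specimen_id": f"F-{i + 1:03d}",
            "group": "cetacean",
            "maturity": "unknown",
            "ocw_mm": ocw,
            "endocranial_volume_cm3": endo,
            "age_ma": float(rng.uniform(34.0, 48.0)),
        })
    return pd.DataFrame(rows)
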