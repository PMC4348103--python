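"""Synthetic marker/metabolite/trait datasets with controlled signal shares.

The generator emulates the structure of a diversity-panel experiment in
which dominant presence/absence markers (scored 1/0, with a spectrum of
minor allele frequencies and some missing calls) and a block of correlated,
nonnegative, right-skewed metabolite abundances (log-normal-like, as NMR
bucket intensities tend to be) are both measured on the same lines, and a
quantitative trait is a linear combination of a few causal columns from
each block plus Gaussian noise.

Two knobs matter most: ``h2``, the fraction of trait variance explained by
the two blocks jointly, and ``signal_share1``, the fraction of that genetic
signal carried by block 1 (the markers).  Block contributions and noise are
rescaled to their target sample variances at generation time, so realized
shares match the specification essentially exactly and are recorded in the
dataset's ``truth``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import InfeasibleSpecError, UnknownFixtureError
from .preprocess import standardize_fit
from .tabular_io import SampleTable, write_table

#: seeds for the canonical named fixtures
_FIXTURE_SEED = 20_150_226


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset; all randomness flows from ``seed``."""

    n: int = 150
    m1: int = 200  # markers
    m2: int = 200  # metabolite features
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    n_causal1: int = 20
    n_causal2: int = 20
    signal_share1: float = 0.5
    h2: float = 0.5
    feature_correlation: float = 0.6  # lag-1 correlation within block 2
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise InfeasibleSpecError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.signal_share1 <= 1.0):
            raise InfeasibleSpecError("signal_share1 must lie in [0, 1]")
        if not (0.0 <= self.h2 < 1.0):
            raise InfeasibleSpecError("h2 must lie in [0, 1)")
        if self.n_causal1 > self.m1 or self.n_causal2 > self.m2:
            raise InfeasibleSpecError("more causal features than block columns")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InfeasibleSpecError("missing_rate must lie in [0, 1)")
        if not (-1.0 < self.feature_correlation < 1.0):
            raise InfeasibleSpecError("feature_correlation must lie in (-1, 1)")
        if self.n < 4 or self.m1 < 1 or self.m2 < 1:
            raise InfeasibleSpecError("dataset too small")


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    marker_table: SampleTable
    metabolite_table: SampleTable
    trait_table: SampleTable
    truth: dict = field(default_factory=dict)


def _scale_to_variance(v: np.ndarray, target: float) -> np.ndarray:
    """Rescale a vector to the exact target sample variance (0 -> zero vector)."""
    if target <= 0.0:
        return np.zeros_like(v)
    var = float(np.var(v))
    if var == 0.0:
        raise InfeasibleSpecError(
            "a causal contribution is constant; cannot reach the target variance"
        )
    return v * np.sqrt(target / var)


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one dataset under ``spec``; same seed gives a bit-identical result."""
    spec.validate()
    master = np.random.default_rng(spec.seed)
    r_marker, r_met, r_eff, r_noise = master.spawn(4)
    n, m1, m2 = spec.n, spec.m1, spec.m2

    # markers: Bernoulli with per-column presence frequency in the MAF range
    p = r_marker.uniform(spec.maf_range[0], spec.maf_range[1], size=m1)
    markers = (r_marker.random((n, m1)) < p).astype(float)
    if spec.missing_rate > 0:
        markers[r_marker.random((n, m1)) < spec.missing_rate] = np.nan

    # metabolites: lag-1 correlated Gaussian, exponentiated to skewed abundances
    rho = spec.feature_correlation
    eps = r_met.standard_normal((n, m2))
    Z = np.empty((n, m2))
    Z[:, 0] = eps[:, 0]
    for k in range(1, m2):
        Z[:, k] = rho * Z[:, k - 1] + np.sqrt(1.0 - rho**2) * eps[:, k]
    metabolites = np.exp(0.5 * Z)

    # trait: linear in standardized causal columns, block variances controlled
    Z1, _ = standardize_fit(markers, source="full-data")
    Z2, _ = standardize_fit(metabolites, source="full-data")
    causal1 = np.sort(r_eff.choice(m1, size=spec.n_causal1, replace=False))
    causal2 = np.sort(r_eff.choice(m2, size=spec.n_causal2, replace=False))
    b1 = r_eff.standard_normal(spec.n_causal1)
    b2 = r_eff.standard_normal(spec.n_causal2)
    g1 = _scale_to_variance(Z1[:, causal1] @ b1, spec.signal_share1 * spec.h2)
    g2 = _scale_to_variance(Z2[:, causal2] @ b2, (1.0 - spec.signal_share1) * spec.h2)
    noise = _scale_to_variance(r_noise.standard_normal(n), 1.0 - spec.h2)
    trait = g1 + g2 + noise
    var_y = float(np.var(trait))

    ids = [f"S{i + 1:04d}" for i in range(n)]
    dataset = SimulatedDataset(
        spec=spec,
        marker_table=SampleTable(
            ids, [f"M{j + 1:04d}" for j in range(m1)], markers, "marker"
        ),
        metabolite_table=SampleTable(
            ids, [f"B{j + 1:04d}" for j in range(m2)], metabolites, "metabolite"
        ),
        trait_table=SampleTable(ids, ["trait"], trait[:, None], "trait"),
        truth={
            "causal_block1": causal1.tolist(),
            "causal_block2": causal2.tolist(),
            "coef_block1": b1.tolist(),
            "coef_block2": b2.tolist(),
            "realized_share_block1": float(np.var(g1)) / var_y,
            "realized_share_block2": float(np.var(g2)) / var_y,
            "realized_h2": float(np.var(g1 + g2)) / var_y,
        },
    )
    return dataset


FIXTURES = {
    # fast everyday fixture for tests and docs
    "tiny": SimulationSpec(
        n=30, m1=20, m2=15, n_causal1=4, n_causal2=3, missing_rate=0.02,
        seed=_FIXTURE_SEED,
    ),
    # dimensions of the HEALTHGRAIN wheat diversity panel: 151 varieties,
    # 843 DArT markers before QC, 620 NMR bucket features
    "wheat": SimulationSpec(
        n=151, m1=843, m2=620, n_causal1=40, n_causal2=30, missing_rate=0.02,
        seed=_FIXTURE_SEED + 1,
    ),
}


def make_fixture(name: str) -> SimulatedDataset:
    """Generate one of the canonical seeded datasets ("tiny" or "wheat")."""
    if name not in FIXTURES:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; expected one of {sorted(FIXTURES)}"
        )
    return simulate(FIXTURES[name])


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Write the three CSV tables plus a JSON truth file for recovery tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(dataset.marker_table, out / "markers.csv")
    write_table(dataset.metabolite_table, out / "metabolites.csv")
    write_table(dataset.trait_table, out / "traits.csv")
    payload = {"spec": asdict(dataset.spec), "truth": dataset.truth}
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
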