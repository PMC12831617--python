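"""Synthetic two-group multi-omics cohorts with known ground truth.

The generator emulates a targeted MS feature table for a case/control
serum study: a fixed cohort of 40 cases vs 49 controls measured on
three layers (100 proteins, 82 N-glycans, 60 metabolites), log-normal
intensities, correlated blocks of co-regulated features within each
layer, a planted set of differential features with a specified
standardized effect size on the log scale, and <1% missingness.

Model: within each layer, log-abundances follow a multivariate Gaussian
with unit variance and exchangeable correlation ``block_rho`` inside
consecutive blocks of ``block_size`` features (zero correlation across
blocks and across layers).  An informative feature's log-mean is
shifted by ``d`` standard deviations in cases.  Values are
exponentiated onto the intensity scale around a per-feature baseline
log-intensity unless ``log_scale`` keeps them Gaussian.  Because the
shift is a location shift of a Gaussian with unit variance in both
groups, the single-feature ROC AUC has the closed form Phi(d/sqrt(2)),
which the tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import SpecError
from .tables import (
    LAYER_PREFIX,
    LAYERS,
    OmicsTable,
    PhenotypeLabels,
    write_labels,
    write_omics_table,
)
import pandas as pd


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study conditions the generator emulates:
    40 cases / 49 controls, layer sizes 100/82/60, sub-1% missingness.
    """

    n_case: int = 40
    n_control: int = 49
    layer_sizes: tuple[int, int, int] = (100, 82, 60)
    n_informative: int = 24
    effect_size: float = 1.0
    block_size: int = 10
    block_rho: float = 0.3
    missing_rate: float = 0.005
    log_scale: bool = False
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.layer_sizes)
        if self.n_informative > total:
            raise SpecError(
                f"n_informative={self.n_informative} exceeds total features {total}"
            )
        if not (0 <= self.block_rho < 1):
            raise SpecError("block_rho must lie in [0, 1)")
        if not (0 <= self.missing_rate <= 1):
            raise SpecError("missing_rate must lie in [0, 1]")
        if self.n_case < 1 or self.n_control < 1:
            raise SpecError("both groups need at least one sample")
        if self.block_size < 1:
            raise SpecError("block_size must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth: which features are informative and how much."""

    informative_features: set[str]
    effect_size_of: dict[str, float] = field(default_factory=dict)


def _feature_ids(layer_sizes) -> list[str]:
    ids = []
    for layer, size in zip(LAYERS, layer_sizes):
        prefix = LAYER_PREFIX[layer]
        width = len(str(max(size, 1)))
        ids.extend(f"{prefix}F{j + 1:0{width}d}" for j in range(size))
    return ids


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[OmicsTable, PhenotypeLabels, SyntheticTruth]:
    """Draw one cohort; fully reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case + spec.n_control
    labels = np.concatenate([np.ones(spec.n_case, int), np.zeros(spec.n_control, int)])
    sample_ids = [f"HCC_{i + 1:03d}" for i in range(spec.n_case)] + [
        f"CIRR_{i + 1:03d}" for i in range(spec.n_control)
    ]
    feature_ids = _feature_ids(spec.layer_sizes)
    p = len(feature_ids)

    # exchangeable correlation within consecutive blocks, per layer:
    # z_ij = sqrt(rho) * g_block + sqrt(1-rho) * e_ij  -> unit variance
    z = np.empty((n, p))
    col = 0
    for size in spec.layer_sizes:
        n_blocks = int(np.ceil(size / spec.block_size)) if size else 0
        shared = rng.standard_normal((n, n_blocks))
        noise = rng.standard_normal((n, size))
        for j in range(size):
            b = j // spec.block_size
            z[:, col + j] = (
                np.sqrt(spec.block_rho) * shared[:, b]
                + np.sqrt(1.0 - spec.block_rho) * noise[:, j]
            )
        col += size

    informative_idx = rng.choice(p, size=spec.n_informative, replace=False)
    informative_idx.sort()
    truth = SyntheticTruth(
        informative_features={feature_ids[j] for j in informative_idx},
        effect_size_of={feature_ids[j]: spec.effect_size for j in informative_idx},
    )
    for j in informative_idx:
        z[labels == 1, j] += spec.effect_size  # shift of d sigma on log scale

    if spec.log_scale:
        values = z
    else:
        baselines = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=p)
        values = np.exp(baselines[None, :] + z)

    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        values = values.astype(float)
        values[mask] = np.nan

    table = OmicsTable(
        pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    )
    return table, PhenotypeLabels(sample_ids, labels), truth


# ---------------------------------------------------------------------------
# deterministic miniature cohorts for unit tests and examples
# ---------------------------------------------------------------------------

_FIXTURE_SPECS = {
    # 20 samples x 30 features, a couple of moderate planted effects
    "mini": SyntheticSpec(
        n_case=10,
        n_control=10,
        layer_sizes=(12, 10, 8),
        n_informative=3,
        effect_size=1.5,
        block_size=5,
        block_rho=0.2,
        missing_rate=0.005,
    ),
    # one very strong feature: alone it achieves CV AUC > 0.95
    "separable": SyntheticSpec(
        n_case=20,
        n_control=20,
        layer_sizes=(10, 10, 10),
        n_informative=1,
        effect_size=4.0,
        block_size=5,
        block_rho=0.2,
        missing_rate=0.0,
    ),
    # pure null: no informative features
    "null": SyntheticSpec(
        n_case=10,
        n_control=12,
        layer_sizes=(10, 10, 10),
        n_informative=0,
        effect_size=0.0,
        block_size=5,
        block_rho=0.2,
        missing_rate=0.0,
    ),
}


def fixture_suite(
    seed: int, out_dir: str | Path | None = None
) -> dict[str, tuple[OmicsTable, PhenotypeLabels, SyntheticTruth]]:
    """Small named cohorts for tests; optionally written as delimited text.

    Each fixture's seed is derived deterministically from ``seed`` and
    the fixture name, so the same call produces byte-identical files.
    """
    out = {}
    for i, (name, base) in enumerate(sorted(_FIXTURE_SPECS.items())):
        child = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        out[name] = generate_cohort(replace(base, seed=child))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, (table, labels, truth) in out.items():
            write_omics_table(table, out_dir / f"{name}_table.tsv")
            write_labels(labels, out_dir / f"{name}_labels.tsv")
            pd.DataFrame(
                {
                    "feature_id": sorted(truth.informative_features),
                    "effect_size": [
                        truth.effect_size_of[f]
                        for f in sorted(truth.informative_features)
                    ],
                }
            ).to_csv(out_dir / f"{name}_truth.tsv", sep="\t", index=False)
    return out
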