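"""Synthetic labeled protein sequences emulating the benchmark's class shifts.

The generator stands in for the deposited solubility benchmark so the whole
pipeline is testable offline. Per class it models

* sequence length as a log-normal (rounded, floor 30 residues) whose
  log-median and log-sigma are set from the published per-class length
  quartiles: soluble median 209 with quartiles [129, 338], insoluble 277
  with [172, 426] (the soluble quartiles are near-symmetric on the log
  scale, which is what motivates the log-normal family);
* residue composition as a Dirichlet draw centered on the class's published
  per-residue median frequencies (renormalized onto the simplex), with a
  shared concentration parameter controlling between-protein variability;
* residue order as a uniformly random permutation of the multinomial counts,
  so order-dependent descriptors (the aggregation ratio) are emergent rather
  than modeled.

It reproduces the benchmark's direction of class differences (soluble
proteins shorter; D/E/K enriched in soluble, C/R in insoluble) and the
approximate within-class spread of the negative-charge proportion; it makes
no attempt to mimic real protein grammar, domains, or homology structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
from scipy import stats

from .sequence_io import INSOLUBLE, SOLUBLE, LabeledDataset, ProteinRecord
from .residue_tables import CANONICAL_RESIDUES

# Published per-class length quartiles (Q1, median, Q3), residues.
LENGTH_QUARTILES = {
    SOLUBLE: (129.0, 209.0, 338.0),
    INSOLUBLE: (172.0, 277.0, 426.0),
}

# Published per-class median residue frequencies (canonical alphabet order
# A C D E F G H I K L M N P Q R S T V W Y); renormalized before sampling.
CLASS_COMPOSITION_MEDIANS = {
    SOLUBLE: {
        "A": 0.07273, "C": 0.01017, "D": 0.05721, "E": 0.07064, "F": 0.03636,
        "G": 0.06195, "H": 0.02381, "I": 0.05128, "K": 0.06019, "L": 0.09091,
        "M": 0.02174, "N": 0.03922, "P": 0.04244, "Q": 0.03768, "R": 0.05350,
        "S": 0.06349, "T": 0.05263, "V": 0.06140, "W": 0.01000, "Y": 0.03061,
    },
    INSOLUBLE: {
        "A": 0.07650, "C": 0.01282, "D": 0.05473, "E": 0.06529, "F": 0.03704,
        "G": 0.06383, "H": 0.02439, "I": 0.05333, "K": 0.05350, "L": 0.09195,
        "M": 0.02174, "N": 0.04000, "P": 0.04494, "Q": 0.03643, "R": 0.05894,
        "S": 0.06630, "T": 0.05263, "V": 0.06349, "W": 0.01031, "Y": 0.02913,
    },
}

# Dirichlet concentration: fixed so that the modelled within-class IQR of the
# negative-charge proportion matches the published soluble IQR (~0.041) once
# the multinomial sampling variance at the modelled lengths is accounted for
# (derivation in docs/methods.md).
DEFAULT_CONCENTRATION = 500.0

DEFAULT_MIN_LENGTH = 30
_Z_Q3 = float(stats.norm.ppf(0.75))


def _length_params(q1: float, median: float, q3: float) -> tuple[float, float]:
    """(log-median, log-sigma) with sigma set from the Q3/median ratio."""
    return log(median), log(q3 / median) / _Z_Q3


@dataclass
class SyntheticConfig:
    n_soluble: int = 5000
    n_insoluble: int = 5000
    length_log_median: dict[str, float] = field(default_factory=dict)
    length_log_sigma: dict[str, float] = field(default_factory=dict)
    composition_mean: dict[str, np.ndarray] = field(default_factory=dict)
    concentration: float = DEFAULT_CONCENTRATION
    min_length: int = DEFAULT_MIN_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_soluble < 1 or self.n_insoluble < 1:
            raise ValueError("class sizes must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        for cls, sigma in self.length_log_sigma.items():
            if sigma <= 0:
                raise ValueError(f"log-sigma for {cls} must be positive")
        for cls, mean in self.composition_mean.items():
            mean = np.asarray(mean, dtype=float)
            if mean.shape != (20,) or (mean < 0).any() or abs(mean.sum() - 1.0) > 1e-9:
                raise ValueError(f"composition mean for {cls} must lie on the 20-simplex")
            self.composition_mean[cls] = mean


def default_config(
    n_soluble: int = 5000, n_insoluble: int = 5000, seed: int = 0
) -> SyntheticConfig:
    """Generator calibrated to the published class-conditional summaries."""
    log_median, log_sigma, comp = {}, {}, {}
    for cls in (SOLUBLE, INSOLUBLE):
        mu, sigma = _length_params(*LENGTH_QUARTILES[cls])
        log_median[cls] = mu
        log_sigma[cls] = sigma
        med = np.array(
            [CLASS_COMPOSITION_MEDIANS[cls][a] for a in CANONICAL_RESIDUES]
        )
        comp[cls] = med / med.sum()
    return SyntheticConfig(
        n_soluble=n_soluble,
        n_insoluble=n_insoluble,
        length_log_median=log_median,
        length_log_sigma=log_sigma,
        composition_mean=comp,
        seed=seed,
    )


_RESIDUE_BYTES = np.frombuffer(CANONICAL_RESIDUES.encode("ascii"), dtype=np.uint8)


def _sample_class(
    rng: np.random.Generator,
    n: int,
    cls: str,
    config: SyntheticConfig,
    id_prefix: str,
) -> list[ProteinRecord]:
    mu = config.length_log_median[cls]
    sigma = config.length_log_sigma[cls]
    lengths = np.maximum(
        np.rint(rng.lognormal(mean=mu, sigma=sigma, size=n)).astype(int),
        config.min_length,
    )
    alpha = config.concentration * config.composition_mean[cls]
    comps = rng.dirichlet(alpha, size=n)
    records = []
    width = len(str(n))
    for i in range(n):
        counts = rng.multinomial(lengths[i], comps[i])
        residues = np.repeat(_RESIDUE_BYTES, counts)
        rng.shuffle(residues)
        records.append(
            ProteinRecord(
                id=f"{id_prefix}_{i:0{width}d}",
                sequence=residues.tobytes().decode("ascii"),
                label=cls,
            )
        )
    return records


def sample_dataset(config: SyntheticConfig | None = None) -> LabeledDataset:
    """Draw a labeled dataset (soluble block then insoluble block)."""
    config = config or default_config()
    rng = np.random.default_rng(config.seed)
    records = _sample_class(rng, config.n_soluble, SOLUBLE, config, "sol")
    records += _sample_class(rng, config.n_insoluble, INSOLUBLE, config, "ins")
    return LabeledDataset(
        records=records,
        provenance={
            "generator": "soldissect.synthetic.sample_dataset",
            "seed": config.seed,
            "n_soluble": config.n_soluble,
            "n_insoluble": config.n_insoluble,
        },
    )


def sample_null_dataset(n: int, config: SyntheticConfig | None = None) -> LabeledDataset:
    """n records per class, all drawn from one shared generative model.

    Sequences come from the soluble-parameter model regardless of label and
    labels are assigned by random shuffle, so every feature is independent of
    the label — the null condition for type-I / FDR behaviour checks.
    """
    if n < 1:
        raise ValueError("n (records per class) must be >= 1")
    config = config or default_config()
    rng = np.random.default_rng(config.seed)
    records = _sample_class(rng, 2 * n, SOLUBLE, config, "null")
    labels = np.array([SOLUBLE] * n + [INSOLUBLE] * n, dtype=object)
    rng.shuffle(labels)
    relabeled = [
        ProteinRecord(id=r.id, sequence=r.sequence, label=lab)
        for r, lab in zip(records, labels)
    ]
    return LabeledDataset(
        records=relabeled,
        provenance={
            "generator": "soldissect.synthetic.sample_null_dataset",
            "seed": config.seed,
            "n_per_class": n,
        },
    )
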