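"""The 36 sequence-derived biochemical descriptors.

Per record: 16 global descriptors (length, molecular weight, isoelectric
point, net charge at pH 7, mean Kyte-Doolittle hydropathy, six residue-group
ratios, three Chou-Fasman propensity means, disorder ratio, aggregation
ratio) plus the 20 amino-acid frequencies.

Ambiguous residues (X, B, Z, U, O) are excluded uniformly from every
computation: they do not count toward the effective length L, contribute no
mass/hydropathy/propensity, and break a hydrophobic run. The effective
length L (canonical residues only) is both the ``length`` feature and the
denominator of every frequency and ratio, which keeps sum(freq) == 1 and the
group-ratio/frequency identities exact.

Net charge follows the Henderson-Hasselbalch model over the ionizable
side chains (D, E, C, Y acidic; H, K, R basic) plus the two termini:

    Q(pH) = sum_basic 1/(1+10^(pH-pKa)) - sum_acidic 1/(1+10^(pKa-pH))

which is strictly decreasing in pH; the isoelectric point is its unique root
on [0, 14], found by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .residue_tables import (
    CANONICAL_RESIDUES,
    GROUP_NAMES,
    PKA_SIDE_CHAINS,
    ResiduePropertyTables,
    load_default_tables,
)
from .sequence_io import LabeledDataset, UNLABELED

GLOBAL_FEATURES = (
    "length",
    "molecular_weight",
    "isoelectric_point",
    "net_charge_pH7",
    "mean_hydropathy",
    "pos_ratio",
    "neg_ratio",
    "polar_ratio",
    "hydrophobic_ratio",
    "tiny_ratio",
    "sulfur_ratio",
    "helix_prop_mean",
    "sheet_prop_mean",
    "turn_prop_mean",
    "disorder_ratio",
    "aggregation_ratio",
)
FREQUENCY_FEATURES = tuple(f"freq_{a}" for a in CANONICAL_RESIDUES)
FEATURE_NAMES: tuple[str, ...] = GLOBAL_FEATURES + FREQUENCY_FEATURES

_GROUP_TO_FEATURE = {
    "positive": "pos_ratio",
    "negative": "neg_ratio",
    "polar": "polar_ratio",
    "hydrophobic": "hydrophobic_ratio",
    "tiny": "tiny_ratio",
    "sulfur": "sulfur_ratio",
}

_N_CANONICAL = len(CANONICAL_RESIDUES)
_AMBIG_CODE = _N_CANONICAL  # ambiguity codes map to one shared bucket

# 256-entry byte lookup: canonical -> 0..19, ambiguous -> 20, invalid -> -1.
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _a in enumerate(CANONICAL_RESIDUES):
    _CODE_LUT[ord(_a)] = _i
    _CODE_LUT[ord(_a.lower())] = _i
for _a in "XBZUO":
    _CODE_LUT[ord(_a)] = _AMBIG_CODE
    _CODE_LUT[ord(_a.lower())] = _AMBIG_CODE

_PI_BISECTION_ITERS = 40  # 14 / 2**40 << 1e-4 pH tolerance


class DegenerateSequenceError(ValueError):
    """Sequence has no canonical residues, so ratios are undefined."""


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer codes (0..19 canonical, 20 ambiguous)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.flatnonzero(codes < 0)})
        raise ValueError(f"invalid residue character(s) {bad}")
    return codes


def _canonical_codes(seq: str) -> np.ndarray:
    codes = encode_sequence(seq)
    canon = codes[codes < _N_CANONICAL]
    if canon.size == 0:
        raise DegenerateSequenceError(
            "sequence contains no canonical residues; features are undefined"
        )
    return canon


def _scale_array(mapping: dict[str, float]) -> np.ndarray:
    return np.array([mapping[a] for a in CANONICAL_RESIDUES], dtype=float)


def _group_mask(tables: ResiduePropertyTables, group: str) -> np.ndarray:
    members = tables.groups[group]
    return np.array([a in members for a in CANONICAL_RESIDUES])


def effective_length(seq: str) -> int:
    """Number of canonical residues (ambiguity codes excluded)."""
    return int(_canonical_codes(seq).size)


def residue_counts(seq: str) -> np.ndarray:
    """20-vector of canonical residue counts in canonical alphabet order."""
    return np.bincount(_canonical_codes(seq), minlength=_N_CANONICAL).astype(float)


def aa_frequencies(seq: str, tables: ResiduePropertyTables | None = None) -> np.ndarray:
    """f_a = n_a / L over the 20 canonical residues; sums to 1."""
    counts = residue_counts(seq)
    return counts / counts.sum()


def group_ratios(seq: str, tables: ResiduePropertyTables | None = None) -> dict[str, float]:
    tables = tables or load_default_tables()
    freqs = aa_frequencies(seq)
    return {
        _GROUP_TO_FEATURE[g]: float(freqs[_group_mask(tables, g)].sum())
        for g in GROUP_NAMES
    }


def molecular_weight(seq: str, tables: ResiduePropertyTables | None = None) -> float:
    """Average peptide mass in Da: sum of residue masses plus one water."""
    tables = tables or load_default_tables()
    counts = residue_counts(seq)
    return float(counts @ _scale_array(tables.masses) + tables.water_mass)


def _charge_from_counts(
    counts: np.ndarray, ph: np.ndarray | float, tables: ResiduePropertyTables
) -> np.ndarray | float:
    """Henderson-Hasselbalch net charge for count vectors (vectorized).

    ``counts`` is (..., 20); ``ph`` broadcasts against the leading shape.
    Every sequence contributes one N-terminus (basic) and one C-terminus
    (acidic).
    """
    pka = tables.pka
    idx = {a: CANONICAL_RESIDUES.index(a) for a in PKA_SIDE_CHAINS}
    ph = np.asarray(ph, dtype=float)
    q = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    q = q - 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for a in ("H", "K", "R"):
        q = q + counts[..., idx[a]] / (1.0 + 10.0 ** (ph - pka[a]))
    for a in ("D", "E", "C", "Y"):
        q = q - counts[..., idx[a]] / (1.0 + 10.0 ** (pka[a] - ph))
    return q


def net_charge(seq: str, ph: float = 7.0, tables: ResiduePropertyTables | None = None) -> float:
    """Net charge (elementary charges) at the given pH, termini included."""
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {ph}")
    tables = tables or load_default_tables()
    return float(_charge_from_counts(residue_counts(seq), ph, tables))


def _pi_from_counts(counts: np.ndarray, tables: ResiduePropertyTables) -> np.ndarray:
    lo = np.zeros(counts.shape[:-1], dtype=float)
    hi = np.full(counts.shape[:-1], 14.0, dtype=float)
    for _ in range(_PI_BISECTION_ITERS):
        mid = 0.5 * (lo + hi)
        q = _charge_from_counts(counts, mid, tables)
        pos = q > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


def isoelectric_point(seq: str, tables: ResiduePropertyTables | None = None) -> float:
    """pH at which the Henderson-Hasselbalch net charge is zero (bisection)."""
    tables = tables or load_default_tables()
    counts = residue_counts(seq)[np.newaxis, :]
    return float(_pi_from_counts(counts, tables)[0])


def mean_hydropathy(seq: str, tables: ResiduePropertyTables | None = None) -> float:
    tables = tables or load_default_tables()
    freqs = aa_frequencies(seq)
    return float(freqs @ _scale_array(tables.hydropathy))


def propensity_mean(
    seq: str, structure_class: str, tables: ResiduePropertyTables | None = None
) -> float:
    tables = tables or load_default_tables()
    if structure_class not in tables.propensities:
        raise ValueError(f"unknown structure class {structure_class!r}")
    freqs = aa_frequencies(seq)
    return float(freqs @ _scale_array(tables.propensities[structure_class]))


def disorder_ratio(seq: str, tables: ResiduePropertyTables | None = None) -> float:
    """Fraction of canonical residues with disorder propensity strictly > tau."""
    tables = tables or load_default_tables()
    freqs = aa_frequencies(seq)
    above = _scale_array(tables.disorder_scale) > tables.disorder_threshold
    return float(freqs[above].sum())


def _max_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max())


def aggregation_ratio(seq: str, tables: ResiduePropertyTables | None = None) -> float:
    """Longest hydrophobic run / effective length.

    Ambiguous residues are dropped before the run scan, so an X inside a
    hydrophobic stretch splits it (conservative).
    """
    tables = tables or load_default_tables()
    codes = encode_sequence(seq)
    n_canon = int((codes < _N_CANONICAL).sum())
    if n_canon == 0:
        raise DegenerateSequenceError(
            "sequence contains no canonical residues; features are undefined"
        )
    mask = np.append(_group_mask(tables, "hydrophobic"), False)[codes]
    return _max_run(mask) / n_canon


@dataclass
class FeatureMatrix:
    """n records x 36 named descriptors plus ids and labels."""

    ids: list[str]
    labels: np.ndarray
    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} records x {len(self.feature_names)} features"
            )
        if self.labels.shape != (n,):
            raise ValueError("labels length does not match record count")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return len(self.ids)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return self.values[:, j]

    def class_values(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(soluble, insoluble) value arrays for one feature."""
        col = self.column(name)
        sol = col[self.labels == "soluble"]
        ins = col[self.labels == "insoluble"]
        return sol, ins

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        return df


def extract_features(
    dataset: LabeledDataset, tables: ResiduePropertyTables | None = None
) -> FeatureMatrix:
    """Compute all 36 descriptors for every record (vectorized, order-preserving)."""
    tables = tables or load_default_tables()
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")

    # Encode all sequences into one flat code array with record offsets.
    code_arrays = []
    for rec in dataset:
        try:
            code_arrays.append(encode_sequence(rec.sequence))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    lengths_raw = np.array([c.size for c in code_arrays])
    flat = np.concatenate(code_arrays)
    row_idx = np.repeat(np.arange(n), lengths_raw)

    counts_all = np.zeros((n, _N_CANONICAL + 1), dtype=float)
    np.add.at(counts_all, (row_idx, flat), 1.0)
    counts = counts_all[:, :_N_CANONICAL]
    L = counts.sum(axis=1)
    degenerate = np.flatnonzero(L == 0)
    if degenerate.size:
        bad = dataset.records[degenerate[0]].id
        raise DegenerateSequenceError(
            f"record {bad!r} has no canonical residues; features are undefined"
        )
    freqs = counts / L[:, None]

    values = np.empty((n, len(FEATURE_NAMES)), dtype=float)
    col = {name: j for j, name in enumerate(FEATURE_NAMES)}
    values[:, col["length"]] = L
    values[:, col["molecular_weight"]] = counts @ _scale_array(tables.masses) + tables.water_mass
    values[:, col["isoelectric_point"]] = _pi_from_counts(counts, tables)
    values[:, col["net_charge_pH7"]] = _charge_from_counts(counts, 7.0, tables)
    values[:, col["mean_hydropathy"]] = freqs @ _scale_array(tables.hydropathy)
    for g in GROUP_NAMES:
        values[:, col[_GROUP_TO_FEATURE[g]]] = freqs[:, _group_mask(tables, g)].sum(axis=1)
    for s in ("helix", "sheet", "turn"):
        values[:, col[f"{s}_prop_mean"]] = freqs @ _scale_array(tables.propensities[s])
    above = _scale_array(tables.disorder_scale) > tables.disorder_threshold
    values[:, col["disorder_ratio"]] = freqs[:, above].sum(axis=1)

    hydro_lut = np.append(_group_mask(tables, "hydrophobic"), False)  # ambiguous breaks runs
    agg = np.empty(n, dtype=float)
    for i, codes in enumerate(code_arrays):
        agg[i] = _max_run(hydro_lut[codes]) / L[i]
    values[:, col["aggregation_ratio"]] = agg

    for j, a in enumerate(CANONICAL_RESIDUES):
        values[:, col[f"freq_{a}"]] = freqs[:, j]

    return FeatureMatrix(
        ids=[r.id for r in dataset],
        labels=np.array([r.label for r in dataset], dtype=object),
        values=values,
    )


def feature_vector(seq: str, tables: ResiduePropertyTables | None = None) -> dict[str, float]:
    """All 36 descriptors for a single sequence as a name->value mapping."""
    tables = tables or load_default_tables()
    from .sequence_io import ProteinRecord

    ds = LabeledDataset(records=[ProteinRecord(id="_", sequence=seq, label=UNLABELED)])
    m = extract_features(ds, tables)
    return dict(zip(m.feature_names, m.values[0]))
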