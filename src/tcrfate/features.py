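"""Biophysical featurization of paired alpha/beta TCR sequences.

Each receptor is represented by a fixed-length vector built from its six CDR
loops (CDR1/2/3 of both chains):

* **positional** — the five Atchley factors of the residue occupying each
  loop slot (5 features per slot; 58 slots under the default allocation,
  giving 290 positional features);
* **composition** — the percentage of each loop occupied by 19 of the 20
  amino acids (glycine excluded as the reference; 19 x 6 = 114 features);
* **length** — the loop length in amino acids (6 features);
* **interaction** — for each pair of sequence-adjacent slots within a loop,
  all 25 products of one slot's factor with the neighbour's factor.

CDR1/CDR2 sequences are germline-encoded and come from the V-gene table;
CDR3 features are computed on the junction interior after dropping the two
invariant anchor residues (C ... F/W).  Loops shorter than their slot
allocation are gapped middle-out (N-terminal half left-aligned, C-terminal
half right-aligned); gap entries are masked and set to 0 *after* the
mean-0/variance-1 scaling fitted on training data.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atchley import AMINO_ACIDS, atchley_matrix
from .io import GeneTable, PairedTcr

__all__ = [
    "LOOPS",
    "ALPHA_LOOPS",
    "BETA_LOOPS",
    "DEFAULT_LOOP_SLOTS",
    "FeatureDescriptor",
    "FeatureRegistry",
    "FeatureMatrix",
    "ScalingStats",
    "build_registry",
    "gap_align",
    "featurize",
    "featurize_matrix",
    "fit_scaling",
    "apply_scaling",
]

LOOPS = ("CDR1a", "CDR2a", "CDR3a", "CDR1b", "CDR2b", "CDR3b")
ALPHA_LOOPS = ("CDR1a", "CDR2a", "CDR3a")
BETA_LOOPS = ("CDR1b", "CDR2b", "CDR3b")

#: default slot allocation (58 slots total).  CDR3 slots cover the junction
#: interior: alpha junctions of length 10-17 -> 8-15 interior residues,
#: beta junctions of length 11-18 -> 9-16.
DEFAULT_LOOP_SLOTS: dict[str, int] = {
    "CDR1a": 7,
    "CDR2a": 8,
    "CDR3a": 15,
    "CDR1b": 6,
    "CDR2b": 6,
    "CDR3b": 16,
}

#: composition letters: the 20 standard residues minus the glycine reference
COMPOSITION_LETTERS = tuple(a for a in AMINO_ACIDS if a != "G")

GAP = "-"


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature: kind, loop, slot/factor indices, letter."""

    kind: str  # position_atchley | composition | length | adjacency_interaction
    loop: str
    slot: int | None = None  # 0-based within-loop slot
    factor: int | None = None  # 0-based Atchley factor
    slot2: int | None = None  # second slot of an adjacent pair
    factor2: int | None = None
    letter: str | None = None  # composition only

    @property
    def name(self) -> str:
        if self.kind == "position_atchley":
            return f"pos_{self.loop}_s{self.slot + 1}_F{self.factor + 1}"
        if self.kind == "composition":
            return f"comp_{self.loop}_{self.letter}"
        if self.kind == "length":
            return f"len_{self.loop}"
        return (
            f"int_{self.loop}_s{self.slot + 1}F{self.factor + 1}"
            f"_s{self.slot2 + 1}F{self.factor2 + 1}"
        )


class FeatureRegistry:
    """Ordered, serializable catalogue of the feature vector's columns.

    The order is fixed: positional (loop-major, slot, factor), then
    composition (loop, letter), then lengths (loop), then interactions
    (loop, adjacent slot pair, factor x factor).
    """

    SCHEMA_VERSION = 1

    def __init__(self, loop_slots: Mapping[str, int]):
        for loop in LOOPS:
            n = loop_slots.get(loop, 0)
            if not isinstance(n, (int, np.integer)) or n <= 0:
                raise ValueError(f"slot count for {loop} must be a positive integer, got {n!r}")
        self.loop_slots = {loop: int(loop_slots[loop]) for loop in LOOPS}
        self.descriptors: list[FeatureDescriptor] = []
        self._blocks: dict[tuple[str, str], slice] = {}

        def block(kind: str, loop: str, descs: list[FeatureDescriptor]) -> None:
            start = len(self.descriptors)
            self.descriptors.extend(descs)
            self._blocks[(kind, loop)] = slice(start, len(self.descriptors))

        for loop in LOOPS:
            block(
                "position_atchley",
                loop,
                [
                    FeatureDescriptor("position_atchley", loop, slot=s, factor=f)
                    for s in range(self.loop_slots[loop])
                    for f in range(5)
                ],
            )
        for loop in LOOPS:
            block(
                "composition",
                loop,
                [FeatureDescriptor("composition", loop, letter=a) for a in COMPOSITION_LETTERS],
            )
        for loop in LOOPS:
            block("length", loop, [FeatureDescriptor("length", loop)])
        for loop in LOOPS:
            descs = [
                FeatureDescriptor(
                    "adjacency_interaction", loop, slot=s, slot2=s + 1, factor=f, factor2=g
                )
                for s in range(self.loop_slots[loop] - 1)
                for f in range(5)
                for g in range(5)
            ]
            block("adjacency_interaction", loop, descs)

    # -- structure ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def n_slots(self) -> int:
        return sum(self.loop_slots.values())

    def block_slice(self, kind: str, loop: str) -> slice:
        return self._blocks[(kind, loop)]

    def indices_by_kind(self, kind: str) -> np.ndarray:
        return np.asarray(
            [i for i, d in enumerate(self.descriptors) if d.kind == kind], dtype=int
        )

    def loop_indices(self, loop: str) -> np.ndarray:
        return np.asarray(
            [i for i, d in enumerate(self.descriptors) if d.loop == loop], dtype=int
        )

    def chain_indices(self, chain: str) -> np.ndarray:
        loops = ALPHA_LOOPS if chain == "alpha" else BETA_LOOPS
        return np.concatenate([self.loop_indices(lp) for lp in loops])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": self.SCHEMA_VERSION,
            "loop_slots": self.loop_slots,
            "interaction_scope": "within_loop_adjacent",
            "composition_reference": "G",
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureRegistry":
        return cls(d["loop_slots"])

    @classmethod
    def from_json(cls, path) -> "FeatureRegistry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def build_registry(loop_slots: Mapping[str, int] | None = None) -> FeatureRegistry:
    """Build the default (or a custom) feature registry.

    The default 58-slot allocation yields 290 positional features, 114
    composition features, 6 lengths and 25 interaction features per adjacent
    within-loop slot pair.
    """
    return FeatureRegistry(loop_slots or DEFAULT_LOOP_SLOTS)


def gap_align(seq: str, n_slots: int) -> str:
    """Middle-out gapping of a loop sequence into a fixed slot frame.

    The first ceil(L/2) residues occupy the leftmost slots and the remaining
    floor(L/2) the rightmost; gaps sit in the middle, where CDR loop length
    variation concentrates.
    """
    L = len(seq)
    if L == 0:
        raise ValueError("cannot gap-align an empty sequence")
    if L > n_slots:
        raise ValueError(f"sequence of length {L} exceeds {n_slots} slots: {seq!r}")
    left = math.ceil(L / 2)
    return seq[:left] + GAP * (n_slots - L) + seq[left:]


@dataclass
class FeatureMatrix:
    """cells x features numeric matrix with a gap mask, tied to a registry."""

    cell_ids: list[str]
    registry: FeatureRegistry
    values: np.ndarray
    mask: np.ndarray  # True where the entry comes from a gap slot

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_ids), len(self.registry)):
            raise ValueError("matrix shape does not match cells x registry")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, prefix: str) -> None:
        """Write ``<prefix>.features.tsv`` and sidecar ``<prefix>.mask.tsv``."""
        names = self.registry.names
        pd.DataFrame(self.values, index=self.cell_ids, columns=names).to_csv(
            f"{prefix}.features.tsv", sep="\t", index_label="cell_id"
        )
        pd.DataFrame(self.mask.astype(int), index=self.cell_ids, columns=names).to_csv(
            f"{prefix}.mask.tsv", sep="\t", index_label="cell_id"
        )

    @classmethod
    def from_tsv(cls, prefix: str, registry: FeatureRegistry) -> "FeatureMatrix":
        vals = pd.read_csv(f"{prefix}.features.tsv", sep="\t", index_col="cell_id")
        mask = pd.read_csv(f"{prefix}.mask.tsv", sep="\t", index_col="cell_id")
        return cls(
            cell_ids=[str(i) for i in vals.index],
            registry=registry,
            values=vals.to_numpy(dtype=float),
            mask=mask.to_numpy(dtype=bool),
        )


_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _loop_sequence(tcr: PairedTcr, loop: str, gene_table: GeneTable) -> str:
    if loop == "CDR1a":
        return gene_table.cdr1("alpha", tcr.alpha.v_gene)
    if loop == "CDR2a":
        return gene_table.cdr2("alpha", tcr.alpha.v_gene)
    if loop == "CDR1b":
        return gene_table.cdr1("beta", tcr.beta.v_gene)
    if loop == "CDR2b":
        return gene_table.cdr2("beta", tcr.beta.v_gene)
    # CDR3: drop the invariant anchors (C ... F/W) and featurize the interior
    cdr3 = tcr.alpha.cdr3_aa if loop == "CDR3a" else tcr.beta.cdr3_aa
    return cdr3[1:-1]


def _slot_codes(seq: str, n_slots: int) -> np.ndarray:
    """Integer residue codes per slot; -1 marks a gap."""
    aligned = gap_align(seq, n_slots)
    return np.asarray([_AA_INDEX[c] if c != GAP else -1 for c in aligned], dtype=np.int8)


def featurize_matrix(
    tcrs: Sequence[PairedTcr],
    gene_table: GeneTable,
    registry: FeatureRegistry,
    atchley: np.ndarray | None = None,
) -> FeatureMatrix:
    """Raw (unscaled) feature matrix for a set of QC-passed receptors.

    Featurization is a pure function of (TCR, gene table, registry): identical
    inputs give identical rows, and row order follows input order.  ``atchley``
    overrides the bundled factor table (used by dependency-tracing tests).
    """
    A = atchley_matrix() if atchley is None else np.asarray(atchley, dtype=float)
    n = len(tcrs)
    p = len(registry)
    values = np.zeros((n, p))
    mask = np.zeros((n, p), dtype=bool)

    for loop in LOOPS:
        n_slots = registry.loop_slots[loop]
        seqs: list[str] = []
        cache: dict[str, np.ndarray] = {}
        codes = np.empty((n, n_slots), dtype=np.int8)
        for i, tcr in enumerate(tcrs):
            seq = _loop_sequence(tcr, loop, gene_table)
            seqs.append(seq)
            row = cache.get(seq)
            if row is None:
                try:
                    row = _slot_codes(seq, n_slots)
                except ValueError as err:
                    raise ValueError(f"{loop} of cell {tcr.cell_id!r}: {err}") from None
                cache[seq] = row
            codes[i] = row

        gap = codes < 0
        safe = np.where(gap, 0, codes)
        fac = A[safe]  # n x slots x 5
        fac[gap] = 0.0

        sl = registry.block_slice("position_atchley", loop)
        values[:, sl] = fac.reshape(n, n_slots * 5)
        mask[:, sl] = np.repeat(gap, 5, axis=1)

        sl = registry.block_slice("composition", loop)
        comp_cache: dict[str, np.ndarray] = {}
        block = np.empty((n, len(COMPOSITION_LETTERS)))
        for i, seq in enumerate(seqs):
            row = comp_cache.get(seq)
            if row is None:
                L = len(seq)
                row = np.asarray(
                    [100.0 * seq.count(a) / L for a in COMPOSITION_LETTERS]
                )
                comp_cache[seq] = row
            block[i] = row
        values[:, sl] = block

        sl = registry.block_slice("length", loop)
        values[:, sl] = np.asarray([len(s) for s in seqs], dtype=float)[:, None]

        sl = registry.block_slice("adjacency_interaction", loop)
        if sl.stop > sl.start:
            left = fac[:, :-1, :, None]  # n x (slots-1) x 5 x 1
            right = fac[:, 1:, None, :]  # n x (slots-1) x 1 x 5
            inter = (left * right).reshape(n, (n_slots - 1) * 25)
            pair_gap = gap[:, :-1] | gap[:, 1:]
            values[:, sl] = inter
            mask[:, sl] = np.repeat(pair_gap, 25, axis=1)

    values[mask] = 0.0
    return FeatureMatrix(
        cell_ids=[t.cell_id for t in tcrs], registry=registry, values=values, mask=mask
    )


def featurize(
    tcr: PairedTcr, gene_table: GeneTable, registry: FeatureRegistry
) -> tuple[np.ndarray, np.ndarray]:
    """Raw feature vector and gap mask for a single receptor."""
    fm = featurize_matrix([tcr], gene_table, registry)
    return fm.values[0], fm.mask[0]


@dataclass
class ScalingStats:
    """Per-feature mean/sd fitted on training observations (gaps excluded).

    Features constant on the training data (sd = 0, e.g. an all-gap slot)
    are flagged and map to 0 after scaling.
    """

    mean: np.ndarray
    sd: np.ndarray
    registry_hash: str

    @property
    def zero_variance(self) -> np.ndarray:
        return self.sd == 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "registry_hash": self.registry_hash,
                    "mean": self.mean.tolist(),
                    "sd": self.sd.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ScalingStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=np.asarray(d["mean"]), sd=np.asarray(d["sd"]), registry_hash=d["registry_hash"]
        )


def fit_scaling(matrix: FeatureMatrix) -> ScalingStats:
    """Estimate per-feature mean and sd over non-masked (non-gap) entries.

    Masked entries hold 0 in the raw matrix, so masked-aware moments reduce
    to plain column sums divided by the per-column non-gap count.
    """
    n_valid = (~matrix.mask).sum(axis=0).astype(float)
    ok = n_valid > 0
    mean = np.zeros(matrix.shape[1])
    sd = np.zeros(matrix.shape[1])
    np.divide(matrix.values.sum(axis=0), n_valid, out=mean, where=ok)
    ex2 = np.zeros(matrix.shape[1])
    np.divide((matrix.values**2).sum(axis=0), n_valid, out=ex2, where=ok)
    np.sqrt(np.clip(ex2 - mean**2, 0.0, None), out=sd)
    return ScalingStats(mean=mean, sd=sd, registry_hash=matrix.registry.hash)


def apply_scaling(matrix: FeatureMatrix, stats: ScalingStats) -> FeatureMatrix:
    """Standardize with (frozen) training statistics; gaps become exactly 0.

    When applied to external data the training means/sds are used unchanged,
    so external scores remain on the training scale.
    """
    if stats.registry_hash != matrix.registry.hash:
        raise ValueError(
            "scaling stats were fitted under a different feature registry "
            f"({stats.registry_hash} != {matrix.registry.hash})"
        )
    scaled = matrix.values - stats.mean
    scaled /= np.where(stats.sd > 0, stats.sd, 1.0)
    scaled[:, stats.zero_variance] = 0.0
    scaled[matrix.mask] = 0.0
    return FeatureMatrix(
        cell_ids=list(matrix.cell_ids),
        registry=matrix.registry,
        values=scaled,
        mask=matrix.mask.copy(),
    )
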