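"""Reading, quality control, pairing and clonotyping of single-cell TCR contigs.

Supports the two community contig dialects (10x ``filtered_contig_annotations.csv``
and the AIRR Rearrangement TSV), pairs chains into one alpha/beta receptor per
cell, applies the standard repertoire QC rules, defines amino-acid-level
clonotypes, and identifies cross-donor "TCR twins" (identical clonotypes
observed in exactly two individuals).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TcrChain",
    "PairedTcr",
    "GeneTable",
    "CellRecord",
    "TwinPair",
    "QCReport",
    "TcrFormatError",
    "read_contigs",
    "write_airr",
    "pair_and_qc",
    "clonotype_key",
    "sample_one_per_clone",
    "find_twins",
    "assign_twin_state",
    "load_bundled_gene_table",
]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: fixed QC rule order; the report attributes each cell to its first failing rule
QC_RULES = ("multiplet", "unresolved_genes", "pseudogene", "length_window")


class TcrFormatError(ValueError):
    """A contig file does not conform to the declared dialect."""


@dataclass(frozen=True)
class TcrChain:
    """One TCR contig: a single alpha or beta chain observed in one cell."""

    cell_id: str
    locus: str  # "alpha" | "beta"
    v_gene: str
    j_gene: str
    cdr3_aa: str
    productive: bool

    def __post_init__(self) -> None:
        if self.locus not in ("alpha", "beta"):
            raise ValueError(f"locus must be 'alpha' or 'beta', got {self.locus!r}")
        if self.cdr3_aa and not set(self.cdr3_aa) <= _STANDARD_AA:
            bad = set(self.cdr3_aa) - _STANDARD_AA
            raise ValueError(f"non-standard residues in CDR3 {self.cdr3_aa!r}: {bad}")


@dataclass(frozen=True)
class PairedTcr:
    """A cell's full alpha/beta receptor after QC."""

    cell_id: str
    alpha: TcrChain
    beta: TcrChain
    donor_id: str = ""

    def __post_init__(self) -> None:
        if self.alpha.locus != "alpha" or self.beta.locus != "beta":
            raise ValueError("chain loci do not match their slots")


@dataclass(frozen=True)
class CellRecord:
    """Per-cell metadata used by the association machinery."""

    cell_id: str
    donor_id: str
    clonotype_key: str
    state_label: str
    covariates: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class TwinPair:
    """A clonotype observed in exactly two donors, with per-donor states."""

    clonotype_key: str
    donor_a: str
    donor_b: str
    state_a: str
    state_b: str

    @property
    def concordant(self) -> bool:
        return self.state_a == self.state_b


@dataclass
class QCReport:
    """Counts of cells removed by each QC rule, in application order."""

    n_cells_in: int = 0
    n_cells_out: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in QC_RULES})
    dropped_loci: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"cells in: {self.n_cells_in}", f"cells retained: {self.n_cells_out}"]
        lines += [f"removed ({rule}): {n}" for rule, n in self.removed.items()]
        return "\n".join(lines)


class GeneTable:
    """V-gene reference: CDR1/CDR2 amino acids and pseudogene flags per locus.

    Lookups strip IMGT allele suffixes (``TRBV28*01`` -> ``TRBV28``) because
    contig dialects differ in whether they report alleles.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"locus", "v_gene", "cdr1_aa", "cdr2_aa", "pseudogene"}
        missing = required - set(table.columns)
        if missing:
            raise TcrFormatError(f"gene table missing columns: {sorted(missing)}")
        df = table.copy()
        df["cdr1_aa"] = df["cdr1_aa"].fillna("")
        df["cdr2_aa"] = df["cdr2_aa"].fillna("")
        if df["pseudogene"].dtype == object:
            df["pseudogene"] = df["pseudogene"].astype(str).str.lower().isin(
                ("true", "t", "1", "yes")
            )
        dup = df.duplicated(subset=["locus", "v_gene"])
        if dup.any():
            raise ValueError(f"duplicate v_gene entries: {df.loc[dup, 'v_gene'].tolist()}")
        bad = ~df["pseudogene"] & ((df["cdr1_aa"] == "") | (df["cdr2_aa"] == ""))
        if bad.any():
            raise ValueError("non-pseudogenes must have CDR1 and CDR2 sequences")
        self._df = df
        self._index = {
            (row.locus, row.v_gene): (row.cdr1_aa, row.cdr2_aa, bool(row.pseudogene))
            for row in df.itertuples()
        }

    @classmethod
    def from_csv(cls, path) -> "GeneTable":
        return cls(pd.read_csv(path))

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @staticmethod
    def strip_allele(name: str) -> str:
        return name.split("*", 1)[0]

    def _get(self, locus: str, v_gene: str):
        return self._index.get((locus, self.strip_allele(v_gene)))

    def contains(self, locus: str, v_gene: str) -> bool:
        return self._get(locus, v_gene) is not None

    def is_pseudogene(self, locus: str, v_gene: str) -> bool:
        rec = self._get(locus, v_gene)
        if rec is None:
            raise KeyError(f"V gene not in gene table: {v_gene!r} ({locus})")
        return rec[2]

    def cdr1(self, locus: str, v_gene: str) -> str:
        rec = self._get(locus, v_gene)
        if rec is None:
            raise KeyError(f"V gene not in gene table: {v_gene!r} ({locus})")
        return rec[0]

    def cdr2(self, locus: str, v_gene: str) -> str:
        rec = self._get(locus, v_gene)
        if rec is None:
            raise KeyError(f"V gene not in gene table: {v_gene!r} ({locus})")
        return rec[1]

    def v_genes(self, locus: str, include_pseudogenes: bool = False) -> list[str]:
        return [
            g
            for (loc, g), (_, _, ps) in self._index.items()
            if loc == locus and (include_pseudogenes or not ps)
        ]


def load_bundled_gene_table() -> GeneTable:
    """The bundled SYNTHETIC V-gene table.

    Real IMGT gene names with synthetic (random but fixed) CDR1/CDR2 amino
    acids of realistic lengths — a stand-in for the IMGT reference, sufficient
    for simulation and testing.  Supply the real IMGT-derived table for
    analyses of real data.
    """
    with resources.files("tcrfate.data").joinpath("gene_table_synthetic.csv").open() as fh:
        return GeneTable(pd.read_csv(fh))


# ---------------------------------------------------------------------------
# contig readers / writers
# ---------------------------------------------------------------------------

_LOCUS_MAP = {"TRA": "alpha", "TRB": "beta", "alpha": "alpha", "beta": "beta"}

_TENX_COLS = ("barcode", "chain", "v_gene", "j_gene", "cdr3", "productive")
_AIRR_COLS = ("cell_id", "locus", "v_call", "j_call", "junction_aa", "productive")


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in ("true", "t", "1", "yes")


def read_contigs(path, dialect: str = "tenx_contig_csv") -> list[TcrChain]:
    """Read TCR contigs from a 10x contig CSV or an AIRR Rearrangement TSV.

    Rows from loci other than TRA/TRB (e.g. TRG, TRD, IG) are dropped and
    counted in a log message.
    """
    if dialect in ("tenx_contig_csv", "tenx"):
        df = pd.read_csv(path, dtype=str)
        cols, locus_col, id_col = _TENX_COLS, "chain", "barcode"
        v_col, j_col, cdr3_col = "v_gene", "j_gene", "cdr3"
    elif dialect in ("airr_tsv", "airr"):
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols, locus_col, id_col = _AIRR_COLS, "locus", "cell_id"
        v_col, j_col, cdr3_col = "v_call", "j_call", "junction_aa"
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TcrFormatError(
            f"{dialect} file {path} missing mandatory column(s): {missing}"
        )

    chains: list[TcrChain] = []
    n_dropped = Counter()
    for row in df.itertuples(index=False):
        raw_locus = getattr(row, locus_col)
        locus = _LOCUS_MAP.get(str(raw_locus))
        if locus is None:
            n_dropped[str(raw_locus)] += 1
            continue
        cdr3 = getattr(row, cdr3_col)
        cdr3 = "" if pd.isna(cdr3) or cdr3 in ("None", "nan") else str(cdr3)
        v = getattr(row, v_col)
        j = getattr(row, j_col)
        chains.append(
            TcrChain(
                cell_id=str(getattr(row, id_col)),
                locus=locus,
                v_gene="" if pd.isna(v) or v in ("None", "nan") else str(v),
                j_gene="" if pd.isna(j) or j in ("None", "nan") else str(j),
                cdr3_aa=cdr3,
                productive=_as_bool(getattr(row, "productive")),
            )
        )
    if n_dropped:
        logger.info(
            "dropped %d contig(s) from out-of-scope loci: %s",
            sum(n_dropped.values()),
            dict(n_dropped),
        )
    return chains


def write_airr(pairs: Sequence[PairedTcr], path) -> None:
    """Write paired receptors as an AIRR Rearrangement TSV (two rows per cell)."""
    rows = []
    for p in pairs:
        for chain, locus in ((p.alpha, "TRA"), (p.beta, "TRB")):
            rows.append(
                {
                    "cell_id": p.cell_id,
                    "locus": locus,
                    "v_call": chain.v_gene,
                    "j_call": chain.j_gene,
                    "junction_aa": chain.cdr3_aa,
                    "productive": "T" if chain.productive else "F",
                }
            )
    pd.DataFrame(rows, columns=list(_AIRR_COLS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pairing + QC
# ---------------------------------------------------------------------------

def pair_and_qc(
    chains: Iterable[TcrChain],
    gene_table: GeneTable,
    min_len_a: int = 10,
    max_len_a: int = 17,
    min_len_b: int = 11,
    max_len_b: int = 18,
    donor_ids: Mapping[str, str] | None = None,
) -> tuple[list[PairedTcr], QCReport]:
    """Pair contigs into one receptor per cell and apply repertoire QC.

    Rules, in fixed order (a cell is attributed to its first failing rule):

    1. ``multiplet`` — not exactly one productive alpha and one productive
       beta chain (dual-alpha / dual-beta cells are excluded).
    2. ``unresolved_genes`` — a V or J gene name missing, or the V gene absent
       from the gene table.
    3. ``pseudogene`` — a V gene flagged as pseudogene.
    4. ``length_window`` — CDR3 length outside [min_len_a, max_len_a] (alpha)
       or [min_len_b, max_len_b] (beta); empty CDR3 also fails here.

    Idempotent: re-running on the retained receptors removes nothing.
    """
    by_cell: dict[str, list[TcrChain]] = {}
    for ch in chains:
        by_cell.setdefault(ch.cell_id, []).append(ch)

    report = QCReport(n_cells_in=len(by_cell))
    pairs: list[PairedTcr] = []
    for cell_id in sorted(by_cell):
        group = by_cell[cell_id]
        alphas = [c for c in group if c.locus == "alpha" and c.productive]
        betas = [c for c in group if c.locus == "beta" and c.productive]
        if len(alphas) != 1 or len(betas) != 1:
            report.removed["multiplet"] += 1
            continue
        a, b = alphas[0], betas[0]
        resolved = all([a.v_gene, a.j_gene, b.v_gene, b.j_gene]) and (
            gene_table.contains("alpha", a.v_gene) and gene_table.contains("beta", b.v_gene)
        )
        if not resolved:
            report.removed["unresolved_genes"] += 1
            continue
        if gene_table.is_pseudogene("alpha", a.v_gene) or gene_table.is_pseudogene(
            "beta", b.v_gene
        ):
            report.removed["pseudogene"] += 1
            continue
        if not (min_len_a <= len(a.cdr3_aa) <= max_len_a) or not (
            min_len_b <= len(b.cdr3_aa) <= max_len_b
        ):
            report.removed["length_window"] += 1
            continue
        donor = donor_ids.get(cell_id, "") if donor_ids else ""
        pairs.append(PairedTcr(cell_id=cell_id, alpha=a, beta=b, donor_id=donor))

    report.n_cells_out = len(pairs)
    return pairs, report


# ---------------------------------------------------------------------------
# clonotypes and twins
# ---------------------------------------------------------------------------

_KEY_SEP = "|"


def clonotype_key(tcr: PairedTcr) -> str:
    """Deterministic amino-acid-level clonotype key.

    Concatenates (with allele suffixes stripped) the V-alpha, J-alpha, V-beta
    and J-beta gene names with both CDR3 amino acid sequences; two receptors
    share a key iff all six components match exactly.
    """
    parts = (
        GeneTable.strip_allele(tcr.alpha.v_gene),
        GeneTable.strip_allele(tcr.alpha.j_gene),
        GeneTable.strip_allele(tcr.beta.v_gene),
        GeneTable.strip_allele(tcr.beta.j_gene),
        tcr.alpha.cdr3_aa,
        tcr.beta.cdr3_aa,
    )
    if any(p == "" for p in parts):
        raise ValueError(f"cannot form clonotype key with empty component(s): {parts}")
    return _KEY_SEP.join(parts)


def sample_one_per_clone(cells: Sequence[CellRecord], seed: int) -> list[CellRecord]:
    """Select one cell uniformly at random to represent each expanded clone.

    Clones are (donor_id, clonotype_key) groups; deterministic per seed.
    """
    groups: dict[tuple[str, str], list[CellRecord]] = {}
    for c in cells:
        groups.setdefault((c.donor_id, c.clonotype_key), []).append(c)
    rng = np.random.default_rng(seed)
    out = []
    for key in sorted(groups):
        members = groups[key]
        out.append(members[int(rng.integers(len(members)))])
    return out


def assign_twin_state(member_labels: Sequence[str]) -> str:
    """State of one twin member: the majority cluster over its clone's cells.

    Singletons keep their own cluster; clones expanded across clusters take
    the cluster with the most cells; ties break to the lexicographically
    smallest label (logged).
    """
    if not member_labels:
        raise ValueError("empty member set")
    counts = Counter(member_labels)
    top = max(counts.values())
    winners = sorted(lbl for lbl, n in counts.items() if n == top)
    if len(winners) > 1:
        logger.info("twin-state tie among %s; choosing %r", winners, winners[0])
    return winners[0]


def find_twins(cells: Sequence[CellRecord]) -> list[TwinPair]:
    """Identify TCR twins: clonotypes observed in exactly two distinct donors.

    Clonotypes private to one donor, or spread over three or more donors, are
    excluded.  Each twin member's state is the majority cluster over that
    donor's cells carrying the clonotype (see :func:`assign_twin_state`).
    """
    by_clone: dict[str, dict[str, list[str]]] = {}
    for c in cells:
        by_clone.setdefault(c.clonotype_key, {}).setdefault(c.donor_id, []).append(
            c.state_label
        )
    twins = []
    for key in sorted(by_clone):
        donors = by_clone[key]
        if len(donors) != 2:
            continue
        d_a, d_b = sorted(donors)
        twins.append(
            TwinPair(
                clonotype_key=key,
                donor_a=d_a,
                donor_b=d_b,
                state_a=assign_twin_state(donors[d_a]),
                state_b=assign_twin_state(donors[d_b]),
            )
        )
    return twins
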