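"""Differential amino-acid composition scanning across vertebrate orthogroups.

Given protein sequences grouped into orthogroups with species-to-clade
labels, this module filters orthogroups (single copy, present in a minimum
fraction of species), computes per-sequence amino-acid composition as a
fraction of counted length, tests each (orthogroup x amino acid) for a
compositional difference between two clades (two-sided Welch t-test by
default), and classifies rows volcano-style with a raw p-value cutoff and a
log2 fold-change cutoff (defaults 1e-16 and +/-1).

Composition ("content") is length-normalized: fold changes between clades
must not reflect protein-length differences. Raw residue counts are retained
alongside for per-sequence outputs such as cysteine counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "AMBIGUOUS",
    "OrthogroupTable",
    "CompositionMatrix",
    "load_orthogroups",
    "load_orthodb_flat",
    "filter_orthogroups",
    "compute_composition",
    "differential_composition",
    "classify_volcano",
    "summarize_by_amino_acid",
    "count_residue_in_cds",
]

#: The 20 standard amino acids (one-letter, alphabetical).
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Letters excluded from both numerator and denominator of composition.
AMBIGUOUS = frozenset("XBZU*")

_ALLOWED = frozenset(AMINO_ACIDS) | AMBIGUOUS


@dataclass
class OrthogroupTable:
    """Orthogroups of protein sequences with a species-to-clade map.

    ``orthogroups`` maps orthogroup id -> species id -> list of sequences
    (multi-copy species keep all copies). ``species_universe`` is the
    explicit denominator for presence filtering, taken from the clade map.
    """

    orthogroups: dict[str, dict[str, list[str]]]
    clade_map: dict[str, str]
    species_universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if not self.species_universe:
            self.species_universe = frozenset(self.clade_map)
        for og, by_species in self.orthogroups.items():
            for sp, seqs in by_species.items():
                if sp not in self.clade_map:
                    raise ValueError(f"species {sp!r} in orthogroup {og!r} has no clade")
                for seq in seqs:
                    if not seq:
                        raise ValueError(f"empty sequence for {og!r}/{sp!r}")
                    bad = set(seq.upper()) - _ALLOWED
                    if bad:
                        raise ValueError(
                            f"invalid residue letters {sorted(bad)} in {og!r}/{sp!r}"
                        )

    def n_orthogroups(self) -> int:
        return len(self.orthogroups)

    def n_sequences(self) -> int:
        return sum(len(s) for by in self.orthogroups.values() for s in by.values())


@dataclass
class CompositionMatrix:
    """Per-sequence amino-acid composition.

    ``fractions``: DataFrame indexed by (orthogroup_id, species_id, copy),
    20 columns of content as fraction of counted length (ambiguity letters
    excluded from the denominator). ``counts``: raw residue counts on the
    same index, plus ``counted_length`` and ``excluded`` tallies.
    """

    fractions: pd.DataFrame
    counts: pd.DataFrame
    counted_length: pd.Series
    excluded: pd.Series


def _read_fasta_unique(path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicated FASTA header id {rec.id!r}: ambiguous resolution")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def load_orthogroups(sequences_path, membership_path, clades_path) -> OrthogroupTable:
    """Assemble an OrthogroupTable from FASTA + membership TSV + clade TSV.

    The membership TSV has a header and columns (orthogroup_id, species_id,
    sequence_id); every sequence_id must resolve to a unique FASTA record.
    Duplicate (orthogroup, species) memberships are retained as multi-copy;
    filtering is a separate step.
    """
    seqs = _read_fasta_unique(sequences_path)
    membership = pd.read_csv(membership_path, sep="\t", dtype=str)
    required = {"orthogroup_id", "species_id", "sequence_id"}
    if not required.issubset(membership.columns):
        raise ValueError(f"membership TSV must have columns {sorted(required)}")
    if membership.empty:
        raise ValueError("membership TSV has no rows")
    clades = pd.read_csv(clades_path, sep="\t", dtype=str)
    if not {"species_id", "clade"}.issubset(clades.columns):
        raise ValueError("clade TSV must have columns species_id, clade")
    if clades.empty:
        raise ValueError("clade TSV has no rows")
    clade_map = dict(zip(clades["species_id"], clades["clade"]))

    orthogroups: dict[str, dict[str, list[str]]] = {}
    for row in membership.itertuples(index=False):
        if row.sequence_id not in seqs:
            raise ValueError(f"sequence id {row.sequence_id!r} not found in FASTA")
        if row.species_id not in clade_map:
            raise ValueError(f"species {row.species_id!r} has no clade assignment")
        orthogroups.setdefault(row.orthogroup_id, {}).setdefault(
            row.species_id, []
        ).append(seqs[row.sequence_id])
    return OrthogroupTable(orthogroups=orthogroups, clade_map=clade_map)


def load_orthodb_flat(og2genes_path, sequences_path, clades_path) -> OrthogroupTable:
    """Parse OrthoDB-style flat files (OG2genes tab + FASTA keyed by gene id).

    The OG2genes file is header-less, two tab-separated columns:
    orthogroup id and gene id of the form ``<taxid>_<variant>:<hex>``; the
    species id is the part before the colon. The FASTA must be keyed by the
    full gene id. Network retrieval of OrthoDB releases is out of scope; this
    reads already-downloaded flat files.
    """
    seqs = _read_fasta_unique(sequences_path)
    clades = pd.read_csv(clades_path, sep="\t", dtype=str)
    clade_map = dict(zip(clades["species_id"], clades["clade"]))
    og2genes = pd.read_csv(og2genes_path, sep="\t", header=None,
                           names=["orthogroup_id", "gene_id"], dtype=str)
    orthogroups: dict[str, dict[str, list[str]]] = {}
    for row in og2genes.itertuples(index=False):
        species = row.gene_id.split(":", 1)[0]
        if row.gene_id not in seqs:
            raise ValueError(f"gene id {row.gene_id!r} not found in FASTA")
        if species not in clade_map:
            raise ValueError(f"species {species!r} has no clade assignment")
        orthogroups.setdefault(row.orthogroup_id, {}).setdefault(species, []).append(
            seqs[row.gene_id]
        )
    return OrthogroupTable(orthogroups=orthogroups, clade_map=clade_map)


def filter_orthogroups(table: OrthogroupTable, min_presence: float = 0.90,
                       require_single_copy: bool = True) -> OrthogroupTable:
    """Keep orthogroups that are single copy and sufficiently present.

    Presence is counted against the explicit species universe (from the
    clade map), so the 90% rule is deterministic regardless of which species
    happen to appear in the data.
    """
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must be in (0, 1]")
    if not table.species_universe:
        raise ValueError("empty species universe")
    n_universe = len(table.species_universe)
    kept: dict[str, dict[str, list[str]]] = {}
    for og, by_species in table.orthogroups.items():
        if require_single_copy and any(len(s) != 1 for s in by_species.values()):
            continue
        if len(by_species) < min_presence * n_universe:
            continue
        kept[og] = {sp: list(seqs) for sp, seqs in by_species.items()}
    return OrthogroupTable(orthogroups=kept, clade_map=dict(table.clade_map),
                           species_universe=table.species_universe)


def compute_composition(table: OrthogroupTable) -> CompositionMatrix:
    """Per-sequence amino-acid content as fraction of counted length.

    Ambiguity letters (X, B, Z, U) and stops (*) are excluded from both the
    numerator and the denominator; their per-row tally is reported in
    ``excluded``. A sequence with zero standard residues is an error.
    """
    if not table.orthogroups:
        raise ValueError("empty orthogroup table")
    index = []
    count_rows = []
    excluded = []
    for og in sorted(table.orthogroups):
        for sp in sorted(table.orthogroups[og]):
            for copy, seq in enumerate(table.orthogroups[og][sp]):
                seq = seq.upper()
                counts = np.array([seq.count(a) for a in AMINO_ACIDS])
                if counts.sum() == 0:
                    raise ValueError(
                        f"sequence {og}/{sp}[{copy}] has no standard residues"
                    )
                index.append((og, sp, copy))
                count_rows.append(counts)
                excluded.append(len(seq) - int(counts.sum()))
    idx = pd.MultiIndex.from_tuples(index, names=["orthogroup_id", "species_id", "copy"])
    counts = pd.DataFrame(count_rows, index=idx, columns=list(AMINO_ACIDS))
    counted_length = counts.sum(axis=1)
    fractions = counts.div(counted_length, axis=0)
    return CompositionMatrix(
        fractions=fractions,
        counts=counts,
        counted_length=counted_length,
        excluded=pd.Series(excluded, index=idx, name="excluded"),
    )


def differential_composition(comp: CompositionMatrix, clade_map: dict[str, str],
                             pair: tuple[str, str], test: str = "welch",
                             use_fraction: bool = True) -> pd.DataFrame:
    """Pairwise clade differential-composition test per orthogroup x amino acid.

    For each orthogroup and each of the 20 amino acids: mean content per
    clade, two-sided t-test p-value (Welch by default, pooled-variance with
    ``test='student'``) and log2 fold change of means, first clade over
    second.  Orthogroups with fewer than two sequences in either clade, or a
    zero mean, yield NaN statistics (flagged undefined, never silently
    dropped); classification later maps them to 'ns'.
    """
    clade_a, clade_b = pair
    known = set(clade_map.values())
    for clade in pair:
        if clade not in known:
            raise ValueError(f"unknown clade label {clade!r}")
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")
    values = comp.fractions if use_fraction else comp.counts

    rows = []
    for og, sub in values.groupby(level="orthogroup_id", sort=True):
        sub_clades = sub.index.get_level_values("species_id").map(clade_map)
        a = sub.loc[np.asarray(sub_clades == clade_a)]
        b = sub.loc[np.asarray(sub_clades == clade_b)]
        n_a, n_b = len(a), len(b)
        for aa in AMINO_ACIDS:
            xa, xb = a[aa].to_numpy(float), b[aa].to_numpy(float)
            mean_a = float(np.mean(xa)) if n_a else np.nan
            mean_b = float(np.mean(xb)) if n_b else np.nan
            if n_a and n_b and mean_a > 0 and mean_b > 0:
                log2fc = float(np.log2(mean_a / mean_b))
            elif n_a and n_b and mean_a == mean_b == 0:
                log2fc = 0.0
            else:
                log2fc = np.nan
            if n_a >= 2 and n_b >= 2:
                with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                    # zero-variance groups are expected and mapped to NaN below
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p = stats.ttest_ind(xa, xb, equal_var=(test == "student")).pvalue
                p_value = float(p) if np.isfinite(p) else np.nan
            else:
                p_value = np.nan
            rows.append((og, aa, clade_a, clade_b, mean_a, mean_b, log2fc,
                         p_value, n_a, n_b))
    return pd.DataFrame(rows, columns=["orthogroup_id", "amino_acid", "clade_a",
                                       "clade_b", "mean_a", "mean_b", "log2fc",
                                       "p_value", "n_a", "n_b"])


def classify_volcano(diff: pd.DataFrame, p_cut: float = 1e-16,
                     lfc_cut: float = 1.0) -> pd.DataFrame:
    """Assign volcano_class: increased / decreased / ns.

    increased iff p < p_cut and log2fc > lfc_cut; decreased iff p < p_cut and
    log2fc < -lfc_cut; everything else (including undefined statistics) ns.
    No multiple-testing correction is applied: the scan uses a raw p-value
    cutoff (default 1e-16).
    """
    if not 0 < p_cut < 1:
        raise ValueError("p_cut must be in (0, 1)")
    if lfc_cut <= 0:
        raise ValueError("lfc_cut must be positive")
    out = diff.copy()
    p = out["p_value"].to_numpy(float)
    lfc = out["log2fc"].to_numpy(float)
    sig = np.isfinite(p) & np.isfinite(lfc) & (p < p_cut)
    out["volcano_class"] = np.select(
        [sig & (lfc > lfc_cut), sig & (lfc < -lfc_cut)],
        ["increased", "decreased"], default="ns",
    )
    return out


def summarize_by_amino_acid(diff: pd.DataFrame) -> pd.DataFrame:
    """Count increased / decreased / ns orthogroups per amino acid and clade pair."""
    if "volcano_class" not in diff.columns:
        raise ValueError("differential table is unclassified: run classify_volcano first")
    summary = (
        diff.groupby(["amino_acid", "clade_a", "clade_b"])["volcano_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["increased", "decreased", "ns"], fill_value=0)
        .reset_index()
    )
    summary.columns.name = None
    return summary


def count_residue_in_cds(cds_path, residue: str = "C") -> int:
    """Translate a coding sequence (FASTA, single record) and count a residue.

    Translation stops at the first stop codon; used e.g. to count cysteines
    in a uricase coding sequence.
    """
    records = list(SeqIO.parse(str(cds_path), "fasta"))
    if len(records) != 1:
        raise ValueError("expected exactly one coding sequence record")
    protein = str(Seq(str(records[0].seq)).translate(to_stop=True))
    if residue.upper() not in AMINO_ACIDS:
        raise ValueError(f"{residue!r} is not a standard amino acid")
    return protein.count(residue.upper())
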