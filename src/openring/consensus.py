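"""Consensus-protein design from a multiple sequence alignment.

Workflow that produced the designed protein: reduce a curated alignment so
that no retained pair of sequences exceeds a maximum pairwise identity
(redundancy filtering), then take the majority-rule consensus per column,
recording per-column support for conservation shading.

Identity convention: matches divided by the columns where at least one of
the two sequences has a residue; columns gapped in both are excluded from
the denominator.  Tie-breaking in the consensus uses a fixed residue order
so designed sequences are reproducible, and tied columns are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

GAP = "-"
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
#: fixed tie-break priority (first wins)
TIE_ORDER = AMINO_ACIDS


@dataclass
class MSA:
    """Ordered (id, aligned sequence) records over amino acids + '-' + 'X'."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.sequences)

    def to_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        from Bio import SeqIO
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        if not ids:
            raise ValueError(f"no FASTA records in {path}")
        return cls(ids, seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, s in zip(self.ids, self.sequences):
                fh.write(f">{i}\n{s}\n")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns where either has a residue."""
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    counted = matches = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        counted += 1
        if x == y and x != GAP:
            matches += 1
    if counted == 0:
        return 0.0
    return matches / counted


def filter_max_identity(msa: MSA, threshold: float) -> MSA:
    """Greedy redundancy filtering to a maximum pairwise identity.

    Sequences are scanned in input order; one is kept iff its identity to
    every already-kept sequence is ≤ ``threshold``.  The output therefore has
    no pair above the threshold, and shrinking the threshold never grows it.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    kept_idx: list[int] = []
    for i, seq in enumerate(msa.sequences):
        if all(pairwise_identity(seq, msa.sequences[j]) <= threshold
               for j in kept_idx):
            kept_idx.append(i)
    return MSA([msa.ids[i] for i in kept_idx],
               [msa.sequences[i] for i in kept_idx])


@dataclass(frozen=True)
class ConsensusResult:
    """Majority-rule consensus with per-column support."""

    consensus: str  # ungapped
    column_support: np.ndarray  # per kept column, fraction matching
    kept_columns: np.ndarray  # indices into the MSA columns
    tie_columns: np.ndarray  # kept-column indices where the majority was tied


def consensus_sequence(msa: MSA, gap_majority_rule: str = "drop",
                       tie_order: str = TIE_ORDER) -> ConsensusResult:
    """Per-column majority-rule consensus.

    For each column the most frequent residue among non-gap, non-'X' symbols
    wins; ties are broken by ``tie_order`` (first listed wins) and flagged.
    Columns where gaps are the absolute majority are dropped under the
    ``"drop"`` rule (kept under ``"keep"``); all-gap columns are always
    dropped, with a warning.  Support is the winning residue's share of the
    column's residue (non-gap) symbols.
    """
    if msa.n_sequences < 2:
        raise ValueError("consensus needs at least 2 sequences")
    if gap_majority_rule not in ("drop", "keep"):
        raise ValueError("gap_majority_rule must be 'drop' or 'keep'")
    rank = {aa: i for i, aa in enumerate(tie_order)}

    letters, support, kept, ties = [], [], [], []
    n_all_gap = 0
    for j in range(msa.n_columns):
        col = msa.column(j)
        residues = [c for c in col if c != GAP and c != "X"]
        n_gaps = sum(1 for c in col if c == GAP)
        if not residues:
            n_all_gap += 1
            continue
        if gap_majority_rule == "drop" and n_gaps > msa.n_sequences / 2:
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        top = max(counts.values())
        winners = sorted((c for c, n in counts.items() if n == top),
                         key=lambda c: rank.get(c, len(rank)))
        letters.append(winners[0])
        support.append(top / len(residues))
        kept.append(j)
        if len(winners) > 1:
            ties.append(j)
    if n_all_gap:
        warnings.warn(f"consensus_sequence: dropped {n_all_gap} all-gap column(s)")
    if not letters:
        raise ValueError("no columns survive the gap-majority rule")
    return ConsensusResult(
        consensus="".join(letters),
        column_support=np.array(support),
        kept_columns=np.array(kept, dtype=int),
        tie_columns=np.array(ties, dtype=int),
    )


def conservation_profile(msa: MSA, **kwargs) -> np.ndarray:
    """Per-kept-column support fractions (grayscale conservation shading)."""
    return consensus_sequence(msa, **kwargs).column_support
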