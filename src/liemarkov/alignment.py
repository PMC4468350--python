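"""Multiple sequence alignments with site-pattern compression.

Sequences are stored as IUPAC bitmasks over the canonical A,G,C,T state
order (bit k set = base k compatible), so ambiguity codes and gaps fall
out of the pruning algorithm as partial likelihoods of one on every
compatible state.  Site patterns are deduplicated once and carried as
(pattern, count) pairs; every likelihood in the package works on the
compressed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

__all__ = ["Alignment", "read_alignment", "write_alignment"]

# bit k corresponds to canonical base k (A=1, G=2, C=4, T=8)
_CODE = {
    "A": 1, "G": 2, "C": 4, "T": 8, "U": 8,
    "R": 1 | 2, "Y": 4 | 8, "W": 1 | 8, "S": 2 | 4, "M": 1 | 4, "K": 2 | 8,
    "B": 2 | 4 | 8, "D": 1 | 2 | 8, "H": 1 | 4 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15, "?": 15, ".": 15, "X": 15, "O": 15,
}
_LETTER = {1: "A", 2: "G", 4: "C", 8: "T", 15: "N"}


@dataclass
class Alignment:
    """Aligned DNA sequences as bitmask codes of shape (taxa, sites)."""

    taxa: list[str]
    codes: np.ndarray
    _patterns: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {', '.join(dupes)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, taxa, sequences) -> "Alignment":
        """Build from (upper/lowercase) sequence strings; U maps to T."""
        taxa = list(taxa)
        seqs = [s.upper() for s in sequences]
        if not seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(
                f"ragged alignment: sequence lengths {sorted(lengths)}")
        try:
            codes = np.array([[_CODE[ch] for ch in s] for s in seqs],
                             dtype=np.uint8)
        except KeyError as exc:
            raise ValueError(f"unknown nucleotide symbol {exc}") from None
        return cls(taxa, codes)

    def sequence(self, taxon: str) -> str:
        """The stored sequence, ambiguity collapsed to IUPAC letters."""
        row = self.codes[self.taxa.index(taxon)]
        rev = {v: k for k, v in _CODE.items() if k not in "U-?.XO"}
        return "".join(rev.get(int(c), "N") for c in row)

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site columns and their counts; counts sum to n_sites."""
        if self._patterns is None:
            cols, counts = np.unique(self.codes, axis=1, return_counts=True)
            self._patterns = (cols, counts)
        return self._patterns

    def base_frequencies(self) -> np.ndarray:
        """Empirical frequencies of unambiguous A,G,C,T calls."""
        counts = np.array([(self.codes == 1 << k).sum() for k in range(4)],
                          dtype=float)
        return counts / counts.sum()


def read_alignment(path, fmt: str | None = None) -> Alignment:
    """Read a FASTA or relaxed PHYLIP alignment.

    `fmt` is ``"fasta"`` or ``"phylip"``; by default it is inferred from
    the filename suffix (``.phy``/``.phylip`` vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    if fmt is None:
        fmt = "phylip" if path.suffix in (".phy", ".phylip") else "fasta"
    bio_fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(fmt)
    if bio_fmt is None:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), bio_fmt)
    except ValueError as exc:
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc
    if fmt == "phylip":
        # the relaxed parser tolerates a wrong header; enforce it here
        with open(path) as fh:
            n_taxa, n_sites = (int(tok) for tok in fh.readline().split()[:2])
        got = (len(msa), msa.get_alignment_length())
        if got != (n_taxa, n_sites):
            raise ValueError(
                f"{path}: header declares {n_taxa} taxa x {n_sites} sites "
                f"but file contains {got[0]} taxa x {got[1]} sites")
    return Alignment.from_sequences([r.id for r in msa],
                                    [str(r.seq) for r in msa])


def write_alignment(aln: Alignment, path, fmt: str | None = None) -> None:
    """Write FASTA (unwrapped) or relaxed sequential PHYLIP."""
    path = Path(path)
    if fmt is None:
        fmt = "phylip" if path.suffix in (".phy", ".phylip") else "fasta"
    with open(path, "w") as fh:
        if fmt == "fasta":
            for taxon in aln.taxa:
                fh.write(f">{taxon}\n{aln.sequence(taxon)}\n")
        elif fmt == "phylip":
            fh.write(f" {aln.n_taxa} {aln.n_sites}\n")
            for taxon in aln.taxa:
                fh.write(f"{taxon}  {aln.sequence(taxon)}\n")
        else:
            raise ValueError(f"unsupported alignment format {fmt!r}")
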