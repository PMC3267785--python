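"""DNA alignments, standard-format I/O and site-pattern compression.

Characters are stored internally as 4-bit state masks (A=1, C=2, G=4, T=8);
IUPAC ambiguity codes map to the union of their states and '-', '?' and 'N'
all map to the full mask (gap and undetermined characters are equivalent
under the likelihood: they allow every state).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Alignment",
    "PatternAlignment",
    "AlignmentError",
    "CHAR_TO_MASK",
    "MASK_TO_VECTOR",
    "read_alignment",
    "write_fasta",
    "compress_patterns",
]


class AlignmentError(ValueError):
    pass


CHAR_TO_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15, "?": 15, "X": 15, "O": 15,
}

# mask -> tip conditional vector over (A, C, G, T); mask 0 is invalid
MASK_TO_VECTOR = np.zeros((16, 4))
for _m in range(1, 16):
    for _s in range(4):
        if _m >> _s & 1:
            MASK_TO_VECTOR[_m, _s] = 1.0

_GAP_MASK = 15


@dataclass
class Alignment:
    """Ordered taxa with equal-length DNA sequences."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        norm = []
        length = None
        for taxon, seq in zip(self.taxa, self.sequences):
            seq = seq.upper().replace("?", "-")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"ragged alignment: taxon {taxon!r} has length "
                    f"{len(seq)}, expected {length}")
            for i, ch in enumerate(seq):
                if ch not in CHAR_TO_MASK:
                    raise AlignmentError(
                        f"unknown character {ch!r} in taxon {taxon!r} at site {i}")
            norm.append(seq)
        self.sequences = norm

    @property
    def site_count(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def masks(self) -> np.ndarray:
        """(n_taxa, site_count) uint8 state-mask matrix."""
        lut = np.zeros(256, dtype=np.uint8)
        for ch, m in CHAR_TO_MASK.items():
            lut[ord(ch)] = m
        rows = [lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
                for seq in self.sequences]
        return np.array(rows, dtype=np.uint8)

    def gappyness(self) -> float:
        """Fraction of gap/undetermined characters in the alignment."""
        return float((self.masks() == _GAP_MASK).mean())


@dataclass
class PatternAlignment:
    """Site-pattern-compressed alignment.

    patterns: (n_taxa, n_patterns) state masks of the distinct columns;
    weights: multiplicity of each pattern; site_to_pattern maps every
    original site to its pattern index.  sum(weights) == site_count.
    """

    taxa: list[str]
    patterns: np.ndarray
    weights: np.ndarray
    site_to_pattern: np.ndarray
    site_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.site_count = int(self.weights.sum())

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def tip_masks(self, taxon: str) -> np.ndarray:
        return self.patterns[self.taxa.index(taxon)]

    def tip_vectors(self, taxon: str) -> np.ndarray:
        """(n_patterns, 4) conditional vectors for a tip (cached)."""
        cache = self.__dict__.setdefault("_tip_vector_cache", {})
        if taxon not in cache:
            cache[taxon] = MASK_TO_VECTOR[self.tip_masks(taxon)]
        return cache[taxon]

    def tip_gap_bits(self, taxon: str) -> np.ndarray:
        """Boolean vector: True where the tip is gap/undetermined (cached)."""
        cache = self.__dict__.setdefault("_tip_gap_cache", {})
        if taxon not in cache:
            cache[taxon] = self.tip_masks(taxon) == _GAP_MASK
        return cache[taxon]


def compress_patterns(aln: Alignment) -> PatternAlignment:
    """Merge identical columns and record multiplicities.

    Identical sites contribute identical per-site likelihoods, so the
    per-pattern log likelihood is computed once and multiplied by the
    pattern weight.  Pattern order is first-occurrence order, which fixes
    the summation order of downstream likelihood accumulation.
    """
    if aln.n_taxa == 0 or aln.site_count == 0:
        raise AlignmentError("empty alignment")
    masks = aln.masks()
    cols = np.ascontiguousarray(masks.T)
    view = cols.view([("", cols.dtype)] * cols.shape[1]).ravel()
    _, first_idx, inverse = np.unique(view, return_index=True, return_inverse=True)
    # reorder unique patterns by first occurrence so output is input-ordered
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    site_to_pattern = rank[inverse]
    patterns = cols[np.sort(first_idx)].T.copy()
    weights = np.bincount(site_to_pattern, minlength=patterns.shape[1])
    return PatternAlignment(list(aln.taxa), patterns, weights.astype(np.int64),
                            site_to_pattern.astype(np.int64))


# ---------------------------------------------------------------------------
# I/O


def _read_fasta(path: str) -> Alignment:
    from Bio import SeqIO

    taxa, seqs = [], []
    for rec in SeqIO.parse(path, "fasta"):
        taxa.append(rec.id)
        seqs.append(str(rec.seq))
    if not taxa:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(taxa, seqs)


def _read_relaxed_phylip(path: str) -> Alignment:
    """Relaxed sequential PHYLIP: header 'ntaxa nsites', then one
    whitespace-separated 'name sequence' record per line (sequences may
    continue on following lines)."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise AlignmentError(f"bad PHYLIP header in {path}")
        n_taxa, n_sites = int(header[0]), int(header[1])
        taxa, seqs = [], []
        current: list[str] | None = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if current is None or len("".join(current)) >= n_sites:
                parts = line.split(None, 1)
                taxa.append(parts[0])
                current = [parts[1].replace(" ", "")] if len(parts) > 1 else []
                seqs.append(current)
            else:
                current.append(line.replace(" ", ""))
    sequences = ["".join(chunks) for chunks in seqs]
    if len(taxa) != n_taxa:
        raise AlignmentError(
            f"PHYLIP header promises {n_taxa} sequences, found {len(taxa)}")
    for t, s in zip(taxa, sequences):
        if len(s) != n_sites:
            raise AlignmentError(
                f"taxon {t!r} has {len(s)} sites, header promises {n_sites}")
    return Alignment(taxa, sequences)


def read_alignment(path: str, format: str | None = None) -> Alignment:
    """Read a FASTA or relaxed PHYLIP alignment.

    If `format` is None it is inferred: files starting with '>' are FASTA,
    otherwise PHYLIP.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        with open(path) as fh:
            first = fh.readline()
        format = "fasta" if first.startswith(">") else "phylip"
    if format == "fasta":
        return _read_fasta(path)
    if format == "phylip":
        return _read_relaxed_phylip(path)
    raise AlignmentError(f"unknown alignment format {format!r}")


def write_fasta(aln: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n{seq}\n")


def write_phylip(aln: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{aln.n_taxa} {aln.site_count}\n")
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f"{taxon} {seq}\n")
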