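"""Sequence evolution under JC69, alignment masking, and multi-locus I/O.

Alignments are stored with one row per haploid sample and one column per
site.  Cells are IUPAC bitmasks (``A=1, C=2, G=4, T=8``; unions encode
ambiguity codes, ``N=15``), so a cell's value directly gives the set of
bases compatible with the observation — exactly the tip partial vector the
pruning likelihood needs.  The synthetic path only ever produces
``A,C,G,T``; ambiguity codes are accepted on read for real data.

The native multi-locus file format (plain text) is::

    <number of loci>
    <locus name> <n_samples> <length>
    <sample name> <sequence>
    ...

repeated per locus.  Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

import numpy as np

from .coalsim import Genealogy

__all__ = ["LocusAlignment", "evolve_jc69", "mask_failing_positions",
           "mask_cpg", "read_multilocus", "write_multilocus",
           "write_fasta", "read_fasta"]

_CHAR_TO_CODE = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "M": 3, "R": 5, "S": 6, "V": 7, "W": 9, "Y": 10, "H": 11,
    "K": 12, "D": 13, "B": 14, "N": 15,
}
_CODE_TO_CHAR = {v: k for k, v in _CHAR_TO_CODE.items()}

_ENCODE = np.zeros(256, dtype=np.uint8)
for ch, code in _CHAR_TO_CODE.items():
    _ENCODE[ord(ch)] = code
    _ENCODE[ord(ch.lower())] = code

_DECODE = np.full(16, ord("?"), dtype=np.uint8)
for code, ch in _CODE_TO_CHAR.items():
    _DECODE[code] = ord(ch)

A, C, G, T, N = 1, 2, 4, 8, 15


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into bitmask codes; raises on bad chars."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if np.any(codes == 0):
        bad = chr(raw[int(np.argmax(codes == 0))])
        raise ValueError(f"illegal nucleotide character {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


class LocusAlignment:
    """Fixed-length nucleotide alignment for one locus.

    Parameters
    ----------
    name : str
        Locus identifier.
    sample_names : list of str
        Unique row labels, in order.
    data : (n_samples, length) uint8 array or list of str
        Bitmask-encoded sequences (strings are encoded on the fly).
    """

    def __init__(self, name: str, sample_names: list[str], data) -> None:
        self.name = name
        self.sample_names = list(sample_names)
        if len(set(self.sample_names)) != len(self.sample_names):
            raise ValueError(f"locus {name}: duplicate sample names")
        if isinstance(data, (list, tuple)) and data and isinstance(data[0], str):
            lengths = {len(s) for s in data}
            if len(lengths) != 1:
                raise ValueError(f"locus {name}: ragged sequence lengths")
            data = np.vstack([encode(s) for s in data])
        self.data = np.asarray(data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.sample_names):
            raise ValueError(f"locus {name}: data shape mismatch")
        if self.data.shape[1] < 1:
            raise ValueError(f"locus {name}: alignment length must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def sequence(self, sample: str) -> str:
        return decode(self.data[self.sample_names.index(sample)])

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.data]

    def copy(self) -> "LocusAlignment":
        return LocusAlignment(self.name, self.sample_names, self.data.copy())

    def __eq__(self, other) -> bool:
        return (isinstance(other, LocusAlignment)
                and self.name == other.name
                and self.sample_names == other.sample_names
                and np.array_equal(self.data, other.data))


def jc69_probs(t: float) -> tuple[float, float]:
    """JC69 transition probabilities over branch length ``t``.

    Returns ``(p_same, p_each_other)`` with
    ``p_same = 1/4 + 3/4 exp(-4t/3)`` and the remaining mass split evenly
    over the three other bases.
    """
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    e = np.exp(-4.0 * t / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def evolve_jc69(genealogy: Genealogy, length: int,
                rng: np.random.Generator | int,
                name: str = "locus") -> LocusAlignment:
    """Evolve a locus of ``length`` sites along a genealogy under JC69.

    The root sequence is i.i.d. uniform over ``{A,C,G,T}``; each site
    mutates independently along each branch.  Deterministic given the seed.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(rng)
    g = genealogy
    seqs = np.empty((g.n_nodes, length), dtype=np.uint8)  # base indices 0..3
    order = g.postorder()[::-1]  # root first
    seqs[order[0]] = rng.integers(0, 4, size=length, dtype=np.uint8)
    for i in order:
        par = g.parent[i]
        if par < 0:
            continue
        t = g.time[par] - g.time[i]
        p_same, _ = jc69_probs(float(t))
        seq = seqs[par].copy()
        changed = rng.random(length) >= p_same
        k = int(changed.sum())
        if k:
            step = rng.integers(1, 4, size=k, dtype=np.uint8)
            seq[changed] = (seq[changed] + step) % 4
        seqs[i] = seq
    tips = np.left_shift(np.uint8(1), seqs[: g.n_tips])  # to bitmask codes
    return LocusAlignment(name, g.tip_names, tips)


def mask_failing_positions(aln: LocusAlignment,
                           mask: dict[str, object]) -> LocusAlignment:
    """Mask individual (sample, position) cells as N.

    ``mask`` maps sample names to iterables of 0-based positions.  Positions
    out of range, or unknown sample names, raise ``ValueError``.
    """
    out = aln.copy()
    for sample, positions in mask.items():
        if sample not in aln.sample_names:
            raise ValueError(f"unknown sample {sample!r}")
        row = aln.sample_names.index(sample)
        for pos in positions:
            if not (0 <= pos < aln.length):
                raise ValueError(
                    f"position {pos} out of range for locus {aln.name} "
                    f"(length {aln.length})")
            out.data[row, pos] = N
    return out


def mask_cpg(aln: LocusAlignment) -> LocusAlignment:
    """Mask CpG-prone column pairs across the whole alignment.

    For every adjacent column pair ``(i, i+1)``: if any sequence carries an
    unambiguous C at ``i`` and any sequence (the same or another) carries an
    unambiguous G at ``i+1``, both columns are set to N in **all**
    sequences.  This removes within-genome CG dinucleotides as well as
    cross-genome C*/*G configurations, and is idempotent.
    """
    out = aln.copy()
    if aln.length < 2:
        return out
    has_c = np.any(aln.data == C, axis=0)
    has_g = np.any(aln.data == G, axis=0)
    hit = has_c[:-1] & has_g[1:]
    cols = np.zeros(aln.length, dtype=bool)
    cols[:-1] |= hit
    cols[1:] |= hit
    out.data[:, cols] = N
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

class MultiLocusParseError(ValueError):
    pass


def write_multilocus(loci: list[LocusAlignment], path) -> None:
    """Write alignments in the native multi-locus text format."""
    with open(path, "w") as fh:
        fh.write(f"{len(loci)}\n")
        for aln in loci:
            fh.write(f"{aln.name} {aln.n_samples} {aln.length}\n")
            for sample, row in zip(aln.sample_names, aln.data):
                fh.write(f"{sample} {decode(row)}\n")


def read_multilocus(path) -> list[LocusAlignment]:
    """Read a multi-locus file; errors name the offending locus and line."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0

    def next_line() -> str:
        nonlocal pos
        if pos >= len(lines):
            raise MultiLocusParseError(f"{path}: unexpected end of file")
        line = lines[pos]
        pos += 1
        return line

    header = next_line().split()
    try:
        n_loci = int(header[0])
    except (IndexError, ValueError):
        raise MultiLocusParseError(f"{path}:1: expected locus count") from None
    loci = []
    for _ in range(n_loci):
        lineno = pos + 1
        parts = next_line().split()
        if len(parts) != 3:
            raise MultiLocusParseError(
                f"{path}:{lineno}: expected 'name n_samples length'")
        name, n_samples, length = parts[0], int(parts[1]), int(parts[2])
        names, rows = [], []
        for _ in range(n_samples):
            lineno = pos + 1
            sparts = next_line().split()
            if len(sparts) != 2:
                raise MultiLocusParseError(
                    f"{path}:{lineno}: locus {name}: expected "
                    f"'sample sequence'")
            if len(sparts[1]) != length:
                raise MultiLocusParseError(
                    f"{path}:{lineno}: locus {name}: sequence length "
                    f"{len(sparts[1])} != declared {length}")
            try:
                rows.append(encode(sparts[1]))
            except ValueError as exc:
                raise MultiLocusParseError(
                    f"{path}:{lineno}: locus {name}: {exc}") from None
            names.append(sparts[0])
        loci.append(LocusAlignment(name, names, np.vstack(rows)))
    if pos < len(lines) and any(l.strip() for l in lines[pos:]):
        raise MultiLocusParseError(
            f"{path}:{pos + 1}: trailing content after {n_loci} loci")
    return loci


def write_fasta(aln: LocusAlignment, path) -> None:
    """Export one locus as FASTA (interoperability convenience)."""
    with open(path, "w") as fh:
        for sample, row in zip(aln.sample_names, aln.data):
            fh.write(f">{sample}\n{decode(row)}\n")


def read_fasta(path, name: str = "locus") -> LocusAlignment:
    """Import a FASTA file as a single locus alignment."""
    from Bio import SeqIO
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(encode(str(rec.seq)))
    if not names:
        raise ValueError(f"{path}: empty FASTA")
    return LocusAlignment(name, names, np.vstack(rows))
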