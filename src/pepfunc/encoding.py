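"""Peptide I/O and fixed-shape numeric encoding.

Peptides are read from FASTA, binary function annotations from a delimited
label table, and each sequence is converted into the fixed-length residue
feature matrix the network consumes: 50 positions x 40 features (20 one-hot
composition columns + 20 PSSM evolutionary-profile columns, zero-filled or
BLOSUM62-substituted when no profile is available).

Sequences shorter than 50 residues are zero-padded at the C-terminal end;
longer sequences are spliced as N-terminal 25 + C-terminal 25, preserving
both termini where functional motifs of short peptides concentrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

#: Fixed alphabetical ordering of the 20 standard residues; defines the
#: one-hot column layout and the PSSM column order used throughout.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: The 15 therapeutic-function categories of the default vocabulary.
DEFAULT_FUNCTIONS = (
    "AMP", "TXP", "ABP", "AIP", "AVP", "ACP", "AFP", "DDV",
    "CPP", "CCC", "APP", "AAP", "AHTP", "PBP", "QSP",
)

#: Padding placeholder used in length-normalised sequence strings.
PAD_CHAR = "-"

DEFAULT_LENGTH = 50
MIN_RECOMMENDED_LENGTH = 10


class FastaParseError(ValueError):
    pass


class LabelTableError(ValueError):
    pass


class PSSMParseError(ValueError):
    pass


@dataclass(frozen=True)
class FunctionVocabulary:
    """Ordered list of the C function names."""

    names: tuple[str, ...] = DEFAULT_FUNCTIONS

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("function names must be unique")
        if len(self.names) < 2:
            raise ValueError("need at least 2 functions")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class Peptide:
    id: str
    sequence: str
    labels: set[str] = field(default_factory=set)

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"peptide {self.id!r}: empty sequence")


@dataclass
class PSSMProfile:
    """Per-residue 20-column log-odds profile aligned to the raw sequence."""

    residues: str
    scores: np.ndarray  # (len(residues), 20), column order = AMINO_ACIDS

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.residues), 20):
            raise ValueError("PSSM shape does not match residue count")


@dataclass
class EncodedSample:
    """Network-ready representation of one peptide."""

    Xs: np.ndarray    # (L, 40)
    Xt: np.ndarray    # (C, C) identity pattern
    mask: np.ndarray  # (L,) bool, True at real residues


def _check_sequence(seq: str, name: str, strict: bool,
                    min_length: int = MIN_RECOMMENDED_LENGTH) -> None:
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_INDEX:
            if strict:
                raise FastaParseError(
                    f"record {name!r}: non-standard residue {ch!r} at position {pos}")
            warnings.warn(
                f"record {name!r}: non-standard residue {ch!r} at position {pos}; "
                "it will be encoded as an all-zero row", stacklevel=3)
    if len(seq) < min_length:
        msg = (f"record {name!r}: sequence length {len(seq)} is below the "
               f"recommended minimum of {min_length}")
        if strict:
            raise FastaParseError(msg)
        warnings.warn(msg, stacklevel=3)


def read_fasta(path: str | Path, strict: bool = False,
               min_length: int = MIN_RECOMMENDED_LENGTH) -> list[Peptide]:
    """Read peptides from FASTA; labels are left empty.

    Duplicate ids are deterministically suffixed ``.2``, ``.3``, ...
    In strict mode non-standard residues and too-short sequences raise
    :class:`FastaParseError`; by default they only warn.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    counts: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise FastaParseError(f"record {record.id!r}: empty sequence")
        _check_sequence(seq, record.id, strict, min_length)
        n = counts.get(record.id, 0) + 1
        counts[record.id] = n
        pid = record.id if n == 1 else f"{record.id}.{n}"
        peptides.append(Peptide(id=pid, sequence=seq))
    return peptides


def write_fasta(peptides: list[Peptide], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{p.id}\n{p.sequence}\n")


def read_label_table(path: str | Path, vocab: FunctionVocabulary,
                     ids: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Read a delimited binary label table into vocabulary column order.

    The header must contain exactly the vocabulary names (any order); the
    first column holds sample ids. If ``ids`` is given the row order is
    validated and reordered against it.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    cols = list(df.columns)
    missing = [n for n in vocab if n not in cols]
    unknown = [c for c in cols if c not in set(vocab)]
    if missing or unknown:
        raise LabelTableError(
            f"label table columns do not match vocabulary: missing={missing}, "
            f"unknown={unknown}")
    df = df[list(vocab)]
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise LabelTableError(
            f"non-binary value {values[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}")
    table_ids = [str(i) for i in df.index]
    if ids is not None:
        id_set = set(table_ids)
        absent = [i for i in ids if i not in id_set]
        if absent:
            raise LabelTableError(f"label table is missing ids: {absent}")
        order = {i: k for k, i in enumerate(table_ids)}
        values = values[[order[i] for i in ids]]
        table_ids = list(ids)
    return table_ids, values.astype(np.int8)


def write_label_table(ids: list[str], labels: np.ndarray,
                      vocab: FunctionVocabulary, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.DataFrame(np.asarray(labels, dtype=int), index=ids, columns=list(vocab))
    df.index.name = "id"
    df.to_csv(path, sep=sep)


def pad_or_truncate(sequence: str, L: int = DEFAULT_LENGTH) -> tuple[str, np.ndarray]:
    """Length-normalise a sequence to exactly ``L`` positions.

    Shorter sequences are padded at the C-terminal end (padding marked False
    in the mask); longer ones keep the first L/2 and last L/2 residues.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if L % 2 != 0:
        raise ValueError(f"L={L} must be even: the splice rule takes L/2 "
                         "residues from each terminus")
    n = len(sequence)
    if n == L:
        return sequence, np.ones(L, dtype=bool)
    if n < L:
        mask = np.zeros(L, dtype=bool)
        mask[:n] = True
        return sequence + PAD_CHAR * (L - n), mask
    half = L // 2
    return sequence[:half] + sequence[-half:], np.ones(L, dtype=bool)


def one_hot_encode(sequence_L: str, mask: np.ndarray) -> np.ndarray:
    """One-hot composition block: (L, 20), padding rows all-zero.

    Characters outside the 20-letter alphabet at masked-real positions yield
    an all-zero row only if they are the documented non-standard codes;
    anything else raises.
    """
    L = len(sequence_L)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (L,):
        raise ValueError("mask length must equal sequence length")
    out = np.zeros((L, 20))
    for i, ch in enumerate(sequence_L):
        if not mask[i]:
            continue
        j = _AA_INDEX.get(ch)
        if j is not None:
            out[i, j] = 1.0
        elif ch in "BJOUXZ":
            continue  # lenient policy: unknown residue -> zero row
        else:
            raise ValueError(f"unknown character {ch!r} at position {i + 1}")
    return out


def parse_pssm(path: str | Path, sequence: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` dialect).

    Extracts the first 20 log-odds columns per residue, reordered to the
    alphabetical residue layout. If ``sequence`` is given the residue letters
    in the file are cross-checked against it.
    """
    lines = Path(path).read_text().splitlines()
    header_idx = None
    for k, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 40 and all(t in _AA_INDEX for t in toks[:20]):
            header_idx = k
            break
        if len(toks) == 20 and all(t in _AA_INDEX for t in toks):
            header_idx = k
            break
    if header_idx is None:
        raise PSSMParseError(f"{path}: no PSSM header line found")
    file_order = lines[header_idx].split()[:20]
    perm = [file_order.index(a) for a in AMINO_ACIDS]

    residues: list[str] = []
    rows: list[list[float]] = []
    for k in range(header_idx + 1, len(lines)):
        toks = lines[k].split()
        if not toks:
            break
        if not toks[0].isdigit():
            break
        if len(toks) < 22:
            raise PSSMParseError(f"{path}, line {k + 1}: expected at least 22 "
                                 f"columns, found {len(toks)}")
        residues.append(toks[1])
        try:
            scores = [float(t) for t in toks[2:22]]
        except ValueError as exc:
            raise PSSMParseError(f"{path}, line {k + 1}: {exc}") from None
        rows.append([scores[p] for p in perm])
    if not rows:
        raise PSSMParseError(f"{path}: no score rows found")
    if sequence is not None:
        found = "".join(residues)
        if found != sequence:
            pos = next(i for i, (a, b) in enumerate(zip(found, sequence), start=1)
                       if a != b) if len(found) == len(sequence) else None
            raise PSSMParseError(
                f"{path}: PSSM residues disagree with the sequence"
                + (f" at position {pos}" if pos else
                   f" (length {len(found)} vs {len(sequence)})"))
    return PSSMProfile(residues="".join(residues), scores=np.asarray(rows))


def _blosum62_row(ch: str) -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    if ch not in mat.alphabet:
        return np.zeros(20)
    return np.array([mat[ch, a] for a in AMINO_ACIDS], dtype=float)


def encode_sample(peptide: Peptide, pssm: PSSMProfile | None = None,
                  vocab: FunctionVocabulary = FunctionVocabulary(),
                  L: int = DEFAULT_LENGTH,
                  pssm_fallback: str = "zero") -> EncodedSample:
    """Build the (L, 40) residue feature matrix and the (C, C) function input.

    Columns 1-20: one-hot composition; 21-40: PSSM log-odds, spliced or
    padded by the same rule as the sequence. Without a profile the fallback
    fills the block with zeros (default) or BLOSUM62 substitution rows.
    """
    seq = peptide.sequence
    if pssm is not None and len(pssm.residues) != len(seq):
        raise ValueError(
            f"peptide {peptide.id!r}: PSSM has {len(pssm.residues)} rows but the "
            f"sequence has {len(seq)} residues")
    seq_L, mask = pad_or_truncate(seq, L)
    comp = one_hot_encode(seq_L, mask)

    if pssm is not None:
        raw = pssm.scores
    elif pssm_fallback == "zero":
        raw = np.zeros((len(seq), 20))
    elif pssm_fallback == "blosum62":
        raw = np.stack([_blosum62_row(ch) for ch in seq])
    else:
        raise ValueError(f"unknown pssm_fallback {pssm_fallback!r}")

    evo = np.zeros((L, 20))
    n = len(seq)
    if n <= L:
        evo[:n] = raw
    else:
        half = L // 2
        evo[:half] = raw[:half]
        evo[half:] = raw[-half:]

    Xs = np.concatenate([comp, evo], axis=1)
    C = len(vocab)
    return EncodedSample(Xs=Xs, Xt=np.eye(C), mask=mask)


@dataclass
class EncodedDataset:
    """A batch-ready dataset: stacked features, masks and binary labels."""

    ids: list[str]
    Xs: np.ndarray    # (N, L, 40)
    mask: np.ndarray  # (N, L)
    Y: np.ndarray     # (N, C)
    vocab: FunctionVocabulary

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(ids=[self.ids[i] for i in idx], Xs=self.Xs[idx],
                              mask=self.mask[idx], Y=self.Y[idx], vocab=self.vocab)


def encode_dataset(peptides: list[Peptide], labels: np.ndarray | None = None,
                   vocab: FunctionVocabulary = FunctionVocabulary(),
                   L: int = DEFAULT_LENGTH,
                   pssms: dict[str, PSSMProfile] | None = None,
                   pssm_fallback: str = "zero") -> EncodedDataset:
    """Encode a peptide list (optionally with a label matrix) for training."""
    C = len(vocab)
    if labels is None:
        labels = np.zeros((len(peptides), C), dtype=np.int8)
        for i, p in enumerate(peptides):
            for name in p.labels:
                labels[i, vocab.index(name)] = 1
    labels = np.asarray(labels)
    if labels.shape != (len(peptides), C):
        raise ValueError("label matrix shape does not match peptides/vocabulary")
    Xs = np.zeros((len(peptides), L, 40))
    mask = np.zeros((len(peptides), L), dtype=bool)
    for i, p in enumerate(peptides):
        enc = encode_sample(p, pssm=(pssms or {}).get(p.id), vocab=vocab, L=L,
                            pssm_fallback=pssm_fallback)
        Xs[i] = enc.Xs
        mask[i] = enc.mask
    return EncodedDataset(ids=[p.id for p in peptides], Xs=Xs, mask=mask,
                          Y=labels.astype(np.int8), vocab=vocab)
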