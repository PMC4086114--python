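"""Binding-motif representation and parsing.

RNA-binding proteins recognize short (3-30 nt) sequence elements that are
conveniently written either as degenerate IUPAC consensus strings (e.g.
``UGCAUG`` for Fox-1 family proteins, ``YCAY`` for NOVA) or as position
specific scoring matrices (PSSMs) in MEME minimal format.  Both inputs are
normalized here into a single :class:`Motif` object: a column-stochastic
probability matrix over the ordered RNA alphabet (A, C, G, U).

DNA-style input (T instead of U) is silently projected onto the RNA alphabet.
Zero probabilities are floored at ``PROB_FLOOR`` and columns renormalized so
that log-odds scores stay finite; the un-floored matrix is retained because
the information content of a consensus motif is defined on the exact
degeneracy pattern.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGU"
PROB_FLOOR = 1e-3
MIN_MOTIF_LEN = 3
MAX_MOTIF_LEN = 30

#: IUPAC degenerate nucleotide codes mapped to the RNA bases they allow.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}


class MotifError(ValueError):
    """Raised for malformed or invalid motif input."""


@dataclass(frozen=True)
class Motif:
    """A named probability matrix over the RNA alphabet.

    Parameters
    ----------
    id:
        Short unique identifier.
    protein:
        Display name of the binding protein.
    probs:
        Array of shape ``(k, 4)``; row ``i`` is the probability distribution
        of position ``i`` over (A, C, G, U) after pseudocount flooring.
    raw_probs:
        The matrix before flooring (may contain exact zeros).
    origin:
        ``"consensus"`` or ``"pssm"``.
    """

    id: str
    protein: str
    probs: np.ndarray
    raw_probs: np.ndarray
    origin: str
    floored: bool = True
    consensus: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        k = self.probs.shape[0]
        if not (MIN_MOTIF_LEN <= k <= MAX_MOTIF_LEN):
            raise MotifError(
                f"motif {self.id!r}: length {k} outside [{MIN_MOTIF_LEN}, {MAX_MOTIF_LEN}]"
            )
        if self.probs.shape != (k, 4) or self.raw_probs.shape != (k, 4):
            raise MotifError(f"motif {self.id!r}: matrix must have 4 columns (A,C,G,U)")
        if np.any(self.probs < 0) or np.any(self.raw_probs < -1e-12):
            raise MotifError(f"motif {self.id!r}: negative probability")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise MotifError(f"motif {self.id!r}: columns do not sum to 1")
        if self.floored and np.any(self.probs < PROB_FLOOR - 1e-12):
            raise MotifError(f"motif {self.id!r}: entries below pseudocount floor")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def best_kmer(self) -> str:
        """The per-position argmax k-mer (ties broken toward A<C<G<U)."""
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    def worst_kmer(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmin(self.probs, axis=1))


def _floor_matrix(raw: np.ndarray) -> np.ndarray:
    # entries below the floor are pinned to it; the remaining mass is scaled
    # so columns stay stochastic and no entry drops back under the floor
    out = np.empty_like(raw, dtype=float)
    for i, row in enumerate(raw):
        low = row < PROB_FLOOR
        if not low.any():
            out[i] = row / row.sum()
            continue
        keep = 1.0 - PROB_FLOOR * low.sum()
        out[i] = np.where(low, PROB_FLOOR, row * keep / row[~low].sum())
    return out


def parse_iupac_consensus(text: str, id: str, protein: str | None = None) -> Motif:
    """Build a :class:`Motif` from a degenerate IUPAC consensus string.

    A symbol allowing *d* bases assigns probability ``1/d`` to each allowed
    base and 0 elsewhere, before flooring.  T is treated as U.
    """
    if not text:
        raise MotifError("empty consensus string")
    text = text.strip().upper()
    raw = np.zeros((len(text), 4))
    for i, ch in enumerate(text):
        allowed = IUPAC_CODES.get(ch)
        if allowed is None:
            raise MotifError(f"unknown IUPAC symbol {ch!r} at position {i + 1}")
        for b in allowed:
            raw[i, ALPHABET.index(b)] = 1.0 / len(allowed)
    return Motif(
        id=id,
        protein=protein or id,
        probs=_floor_matrix(raw),
        raw_probs=raw,
        origin="consensus",
        consensus=text.replace("T", "U"),
    )


_MEME_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)(?:\s+(\S+))?")
_MEME_MATRIX_RE = re.compile(
    r"^letter-probability matrix:(?:\s+alength=\s*(\d+))?(?:\s+w=\s*(\d+))?"
)


def read_meme_pssms(stream) -> list[Motif]:
    """Read every motif from a MEME minimal-format text stream.

    Accepts the minimal dialect: a ``MEME version`` header, an optional
    ``ALPHABET=`` line (ACGT or ACGU), optional strand/background blocks, and
    one or more ``MOTIF``/``letter-probability matrix`` blocks.  DNA input is
    relabeled to RNA (T column becomes U).  Each matrix row must sum to 1
    within 1e-3.
    """
    lines = [ln.rstrip("\n") for ln in stream]
    if not any(ln.lstrip().startswith("MEME version") for ln in lines):
        raise MotifError("not a MEME minimal file: missing 'MEME version' header")
    for ln in lines:
        s = ln.strip()
        if s.startswith("ALPHABET="):
            alpha = s.split("=", 1)[1].strip().upper()
            if alpha not in ("ACGT", "ACGU"):
                raise MotifError(f"unsupported alphabet {alpha!r} (need ACGT or ACGU)")

    motifs: list[Motif] = []
    i = 0
    while i < len(lines):
        m = _MEME_MOTIF_RE.match(lines[i].strip())
        if not m:
            i += 1
            continue
        motif_id, alt_name = m.group(1), m.group(2)
        i += 1
        # seek the matrix header for this motif
        while i < len(lines) and not lines[i].strip().startswith(
            "letter-probability matrix"
        ):
            if _MEME_MOTIF_RE.match(lines[i].strip()):
                raise MotifError(f"motif {motif_id!r}: missing letter-probability matrix")
            i += 1
        if i == len(lines):
            raise MotifError(f"motif {motif_id!r}: missing letter-probability matrix")
        header = _MEME_MATRIX_RE.match(lines[i].strip())
        declared_w = int(header.group(2)) if header and header.group(2) else None
        i += 1
        rows: list[list[float]] = []
        while i < len(lines):
            s = lines[i].strip()
            if not s or s.startswith(("MOTIF", "URL", "letter-probability")):
                break
            try:
                vals = [float(x) for x in s.split()]
            except ValueError:
                break
            if len(vals) != 4:
                raise MotifError(
                    f"motif {motif_id!r}: matrix row with {len(vals)} values (need 4)"
                )
            if abs(sum(vals) - 1.0) > 1e-3:
                raise MotifError(
                    f"motif {motif_id!r}: row {len(rows) + 1} sums to "
                    f"{sum(vals):.4f}, not 1"
                )
            rows.append(vals)
            i += 1
        if declared_w is not None and declared_w != len(rows):
            raise MotifError(
                f"motif {motif_id!r}: declared w={declared_w} but {len(rows)} rows"
            )
        if not rows:
            raise MotifError(f"motif {motif_id!r}: empty matrix")
        raw = np.array(rows, dtype=float)
        raw = np.clip(raw, 0.0, None)
        raw = raw / raw.sum(axis=1, keepdims=True)
        motifs.append(
            Motif(
                id=motif_id,
                protein=alt_name or motif_id,
                probs=_floor_matrix(raw),
                raw_probs=raw,
                origin="pssm",
            )
        )
    if not motifs:
        raise MotifError("no MOTIF blocks found")
    return motifs


def write_meme(motifs: list[Motif], stream) -> None:
    """Serialize motifs back to MEME minimal format (RNA alphabet)."""
    stream.write("MEME version 4\n\nALPHABET= ACGU\n\n")
    for m in motifs:
        stream.write(f"MOTIF {m.id} {m.protein}\n")
        stream.write(f"letter-probability matrix: alength= 4 w= {m.length}\n")
        for row in m.raw_probs:
            stream.write(" ".join(f"{p:.9f}" for p in row) + "\n")
        stream.write("\n")


def information_content(m: Motif) -> float:
    """Total information content in bits, ``sum_i (2 + sum_b p log2 p)``.

    For consensus-derived motifs the exact (un-floored) degeneracy pattern is
    used, so an all-N motif carries exactly 0 bits and a fully determined one
    2 bits per position.  This scalar operationalizes motif "complexity" for
    the analytic (annotation-free) threshold.
    """
    probs = m.raw_probs if m.origin == "consensus" else m.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(np.where(probs > 0, probs, 1.0)), 0.0)
    ic = float(2.0 * m.length + plogp.sum())
    return max(ic, 0.0)


def load_motif_manifest(path) -> list[Motif]:
    """Load motifs from a TSV manifest: ``id<TAB>protein<TAB>consensus-or-file``.

    A third field containing only IUPAC symbols is parsed as a consensus;
    otherwise it is taken as a path (relative to the manifest) to a MEME file
    whose motifs are all loaded with the given protein name.
    """
    import pathlib

    path = pathlib.Path(path)
    out: list[Motif] = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 3:
            raise MotifError(f"manifest line needs 3 tab-separated fields: {ln!r}")
        mid, protein, src = parts
        if all(c.upper() in IUPAC_CODES for c in src):
            out.append(parse_iupac_consensus(src, id=mid, protein=protein))
        else:
            with open(path.parent / src) as fh:
                for m in read_meme_pssms(fh):
                    # keep the ids from the MEME file; the manifest names the protein
                    out.append(
                        Motif(id=m.id, protein=protein, probs=m.probs,
                              raw_probs=m.raw_probs, origin="pssm")
                    )
    return out
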