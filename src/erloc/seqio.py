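"""Sequence and profile I/O.

Reads FASTA files into validated protein sequences, parses PSI-BLAST ASCII
PSSM files (the ``-out_ascii_pssm`` dialect), and builds row-normalized
residue profiles.  A residue profile is an ``l x 20`` matrix with one row per
sequence position; each row is a probability distribution over the 20
canonical amino acids.  Two profile sources exist:

* ``one_hot`` -- row *j* puts all its mass on the residue observed at
  position *j* (the binary encoding of the sequence itself);
* ``pssm``    -- rows derive from PSI-BLAST log-odds scores squashed through
  the logistic function and renormalized, so that evolutionary information
  replaces the hard one-hot assignment when a profile is available.

Both sources satisfy the same contract (every row sums to 1), which is what
lets downstream feature extraction treat them interchangeably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical internal ordering of the 20 amino acids (alphabetical one-letter).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Letters that occur in real databases but are not canonical amino acids.
NON_CANONICAL = set("BJOUXZ*")

ROW_SUM_TOL = 1e-9


class PSSMParseError(ValueError):
    """Raised when a PSSM file does not follow the expected ASCII layout."""


class PSSMLengthMismatchError(ValueError):
    """Raised when PSSM row count disagrees with the paired sequence length."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence over the 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclass(frozen=True)
class RawPSSM:
    """Raw PSI-BLAST log-odds scores, columns in canonical ordering."""

    sequence_id: str
    scores: np.ndarray  # l x 20, canonical column order

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be an l x 20 matrix")


@dataclass(frozen=True)
class ResidueProfile:
    """Row-stochastic l x 20 residue matrix (one-hot or normalized PSSM)."""

    values: np.ndarray
    source: str  # "one_hot" | "pssm"

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError("profile must be an l x 20 matrix")
        if self.source not in ("one_hot", "pssm"):
            raise ValueError(f"unknown profile source {self.source!r}")
        rows = self.values.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=ROW_SUM_TOL, rtol=0.0):
            raise ValueError("profile rows must sum to 1")

    @property
    def length(self) -> int:
        return self.values.shape[0]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file, excluding records with non-canonical residues.

    Records containing letters outside ACDEFGHIKLMNPQRSTVWY (e.g. B, J, O,
    U, X, Z) are dropped with a warning; remaining records are returned in
    file order with residues upper-cased.
    """
    records: list[ProteinSequence] = []
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        seq = str(rec.seq).upper()
        bad = set(seq) - set(ALPHABET)
        if not seq or bad:
            logger.warning(
                "excluding %s: non-canonical residues %s",
                rec.id, sorted(bad) if bad else "(empty)",
            )
            continue
        records.append(ProteinSequence(id=rec.id, residues=seq))
    if n_seen == 0:
        logger.warning("no FASTA records parsed from %s", path)
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path,
                width: int = 60) -> None:
    """Write sequences to FASTA with fixed line wrapping (deterministic)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, s.length, width):
                fh.write(s.residues[i:i + width] + "\n")


def _is_pssm_header(tokens: list[str]) -> bool:
    if len(tokens) < 20:
        return False
    head = tokens[:20]
    return all(len(t) == 1 and t in ALPHABET for t in head) \
        and sorted(head) == sorted(ALPHABET)


def parse_pssm(path: str | Path, seq: ProteinSequence) -> RawPSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file for ``seq``.

    Only the first 20 numeric columns (the log-odds block) are used; columns
    are re-ordered to the canonical alphabet on read.  Row count must equal
    the sequence length.
    """
    lines = Path(path).read_text().splitlines()
    column_order: list[str] | None = None
    rows: list[list[float]] = []
    for line in lines:
        tokens = line.split()
        if column_order is None:
            if _is_pssm_header(tokens):
                column_order = tokens[:20]
            continue
        if len(tokens) >= 22 and tokens[0].isdigit():
            try:
                rows.append([float(t) for t in tokens[2:22]])
            except ValueError as exc:
                raise PSSMParseError(
                    f"{path}: malformed score row {tokens[0]}"
                ) from exc
    if column_order is None:
        raise PSSMParseError(f"{path}: no PSSM header line found")
    if len(rows) != seq.length:
        raise PSSMLengthMismatchError(
            f"{path}: {len(rows)} rows for sequence {seq.id} "
            f"of length {seq.length}"
        )
    raw = np.asarray(rows, dtype=float)
    # re-order file columns into the canonical internal ordering
    perm = [column_order.index(aa) for aa in ALPHABET]
    return RawPSSM(sequence_id=seq.id, scores=raw[:, perm])


def normalize_pssm(raw: RawPSSM) -> ResidueProfile:
    """Squash log-odds scores to a row-stochastic profile.

    Each score x maps through the logistic 1/(1+e^-x); each row is then
    divided by its sum.  Logistic outputs are strictly positive, so row sums
    never vanish and the row-sum-1 contract holds for any input.
    """
    squashed = 1.0 / (1.0 + np.exp(-raw.scores))
    values = squashed / squashed.sum(axis=1, keepdims=True)
    return ResidueProfile(values=values, source="pssm")


def one_hot_profile(seq: ProteinSequence) -> ResidueProfile:
    """Binary residue encoding: row j has a single 1 at residue r_j."""
    values = np.zeros((seq.length, 20))
    for j, aa in enumerate(seq.residues):
        values[j, AA_INDEX[aa]] = 1.0
    return ResidueProfile(values=values, source="one_hot")


def decode_one_hot(profile: ResidueProfile) -> str:
    """Recover the residue string from a profile by per-row argmax."""
    return "".join(ALPHABET[i] for i in profile.values.argmax(axis=1))


def load_profile(seq: ProteinSequence,
                 pssm_dir: str | Path | None) -> ResidueProfile:
    """Select the residue profile for a sequence.

    If ``pssm_dir`` contains a parseable ``<id>.pssm`` file of matching
    length, the normalized PSSM profile is used; otherwise (missing
    directory, missing file, or parse/length failure, which is logged) the
    one-hot encoding is the fallback.
    """
    if pssm_dir is not None:
        pssm_path = Path(pssm_dir) / f"{seq.id}.pssm"
        if pssm_path.exists():
            try:
                return normalize_pssm(parse_pssm(pssm_path, seq))
            except (PSSMParseError, PSSMLengthMismatchError) as exc:
                logger.warning("falling back to one-hot for %s: %s",
                               seq.id, exc)
    return one_hot_profile(seq)


def load_profiles(seqs: Iterable[ProteinSequence],
                  pssm_dir: str | Path | None) -> list[ResidueProfile]:
    """Vectorized :func:`load_profile`; logs how many used each source."""
    profiles = [load_profile(s, pssm_dir) for s in seqs]
    n_pssm = sum(p.source == "pssm" for p in profiles)
    logger.info("profiles: %d from PSSM, %d one-hot",
                n_pssm, len(profiles) - n_pssm)
    return profiles
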