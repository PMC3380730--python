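"""PSI-BLAST ASCII PSSM profiles and per-residue samples.

A PSSM row holds the log-odds of observing each of the 20 amino acids at
one alignment position of an iterative profile search.  Only the first
20-column block of the ``-out_ascii_pssm`` layout (the log-odds) is
consumed; the second block (weighted observed percentages) is ignored.
Log-odds are squashed into (0, 1) elementwise with the standard logistic
function 1/(1+e^-x) — this scaled matrix is what the integrative profile
encoder consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.special import expit

from pssmpp.aaindex import CANONICAL_AA_ORDER

logger = logging.getLogger(__name__)


class PSSMParseError(ValueError):
    """Malformed ascii-pssm input (bad value count, non-consecutive rows)."""


def logistic_scale(x):
    """Standard logistic 1/(1+e^-x); elementwise, strictly increasing."""
    return expit(x)


@dataclass
class PSSMProfile:
    """A chain's sequence with its L x 20 log-odds matrix.

    ``scaled`` is the logistic-squashed twin of ``log_odds``; columns
    follow :data:`~pssmpp.aaindex.CANONICAL_AA_ORDER` in both.
    """

    chain_id: str
    sequence: str
    log_odds: np.ndarray
    scaled: np.ndarray

    def __post_init__(self):
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.scaled = np.asarray(self.scaled, dtype=float)
        if self.log_odds.shape != (len(self.sequence), 20):
            raise ValueError(
                f"chain {self.chain_id}: log-odds shape {self.log_odds.shape} "
                f"inconsistent with sequence length {len(self.sequence)}"
            )

    @classmethod
    def from_log_odds(cls, chain_id: str, sequence: str, log_odds) -> "PSSMProfile":
        log_odds = np.asarray(log_odds, dtype=float)
        return cls(chain_id, sequence, log_odds, logistic_scale(log_odds))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueSample:
    """One classification unit: a residue position with its binding label."""

    chain_id: str
    position: int  # 1-based
    label: int  # 1 = heme binding


def parse_pssm(stream: TextIO | str | Path, chain_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    The sequence is reconstructed from the residue-letter column; the
    log-odds come from the first 20-column block, re-mapped to the
    canonical amino-acid order using the file's own column header.

    Raises
    ------
    PSSMParseError
        For a row with fewer than 20 parsable values or position indices
        not consecutive from 1, reporting the offending line number.
    """
    if isinstance(stream, Path):
        text = stream.read_text()
        if chain_id is None:
            chain_id = stream.stem
    elif isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    if chain_id is None:
        chain_id = "?"

    lines = text.splitlines()
    header_cols: list[str] | None = None
    rows: list[np.ndarray] = []
    residues: list[str] = []
    expected_index = 1

    for line_no, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if header_cols is None:
            # the column-header line: >= 20 single-letter tokens
            if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20]):
                header_cols = [t.upper() for t in tokens[:20]]
                if sorted(header_cols) != sorted(CANONICAL_AA_ORDER):
                    raise PSSMParseError(
                        f"line {line_no}: column header is not the 20 standard amino acids"
                    )
            continue
        if not tokens[0].lstrip("-").isdigit():
            continue  # footer (K, Lambda, ...) or stray text
        idx = int(tokens[0])
        if idx != expected_index:
            raise PSSMParseError(
                f"line {line_no}: position index {idx}, expected {expected_index}"
            )
        if len(tokens) < 22:
            raise PSSMParseError(
                f"line {line_no}: truncated row ({len(tokens) - 2} of 20 log-odds values)"
            )
        residue = tokens[1].upper()
        try:
            values = np.array([float(t) for t in tokens[2:22]], dtype=float)
        except ValueError as exc:
            raise PSSMParseError(f"line {line_no}: non-numeric log-odds value") from exc
        residues.append(residue)
        rows.append(values)
        expected_index += 1

    if header_cols is None or not rows:
        raise PSSMParseError("no PSSM data rows found")

    log_odds_file_order = np.vstack(rows)
    # remap the file's column order to the canonical order
    perm = [header_cols.index(aa) for aa in CANONICAL_AA_ORDER]
    log_odds = log_odds_file_order[:, perm]
    return PSSMProfile.from_log_odds(chain_id, "".join(residues), log_odds)


def write_pssm(profile: PSSMProfile, path) -> None:
    """Write a profile in the ``-out_ascii_pssm`` dialect :func:`parse_pssm` reads.

    The second 20-column block (weighted percentages) and the two trailing
    statistics columns are emitted as zeros — they carry no information
    used by this package.
    """
    aa_header = "  ".join(CANONICAL_AA_ORDER)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write("            " + aa_header + "   " + aa_header + "\n")
        for i, residue in enumerate(profile.sequence):
            lo = " ".join(f"{int(round(v)):3d}" for v in profile.log_odds[i])
            pct = " ".join(f"{0:3d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {residue} {lo}  {pct}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3172\n")


def read_labels(path) -> list[ResidueSample]:
    """Read per-residue binding labels from TSV (chain_id, position, label)."""
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str})
    required = {"chain_id", "position", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"label file must have columns {sorted(required)}, got {list(df.columns)}")
    return [
        ResidueSample(str(r.chain_id), int(r.position), int(r.label))
        for r in df.itertuples(index=False)
    ]


def write_labels(samples: Iterable[ResidueSample], path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tposition\tlabel\n")
        for s in samples:
            fh.write(f"{s.chain_id}\t{s.position}\t{s.label}\n")


def read_fasta(path) -> dict[str, str]:
    """Read chain sequences from FASTA, keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def cross_check_sequences(profiles: dict[str, PSSMProfile], fasta: dict[str, str]) -> int:
    """Compare profile sequences against FASTA; log each mismatched position.

    Returns the total number of mismatched positions (0 = all consistent).
    Mismatches are warnings, not errors: PSI-BLAST output occasionally
    masks low-complexity residues with X.
    """
    mismatches = 0
    for chain_id, profile in profiles.items():
        ref = fasta.get(chain_id)
        if ref is None:
            logger.warning("chain %s: no FASTA record to cross-check", chain_id)
            continue
        if len(ref) != profile.length:
            logger.warning(
                "chain %s: FASTA length %d != PSSM length %d",
                chain_id, len(ref), profile.length,
            )
        for pos, (a, b) in enumerate(zip(profile.sequence, ref), start=1):
            if a != b:
                logger.warning("chain %s position %d: PSSM %s vs FASTA %s", chain_id, pos, a, b)
                mismatches += 1
    return mismatches


def validate_samples(samples: Sequence[ResidueSample], profiles: dict[str, PSSMProfile]) -> None:
    """Check every sample's position lies within its chain."""
    for s in samples:
        profile = profiles.get(s.chain_id)
        if profile is None:
            raise ValueError(f"sample references unknown chain {s.chain_id!r}")
        if not 1 <= s.position <= profile.length:
            raise ValueError(
                f"chain {s.chain_id}: position {s.position} outside [1, {profile.length}]"
            )


def residues_and_labels(
    samples: Sequence[ResidueSample], profiles: dict[str, PSSMProfile]
) -> tuple[list[str], np.ndarray]:
    """Per-sample residue letters and label vector, aligned with ``samples``."""
    residues = [profiles[s.chain_id].sequence[s.position - 1] for s in samples]
    labels = np.array([s.label for s in samples], dtype=int)
    return residues, labels
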