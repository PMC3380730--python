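"""AAindex1 physicochemical scales: parsing, normalization, AUC ranking.

An AAindex1 record assigns one real number to each of the 20 standard
amino acids (a "scale"): hydrophobicity, secondary-structure propensity,
linker preference and so on.  Scales are z-normalized across the 20
amino-acid types (zero mean, unit *population* standard deviation) and
their discriminative power for a labelled residue set is measured as the
ROC AUC of the per-residue assigned value against the binary label — no
classifier is trained, so no cross-validation is involved at this stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

#: Fixed canonical residue order used for every 20-vector in this package.
CANONICAL_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_AA_TO_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA_ORDER)}

#: Numeric tolerance for the zero-mean / unit-std contract of normalized scales.
NORMALIZATION_TOL = 1e-10


class AAindexParseError(ValueError):
    """Malformed AAindex1 record (wrong value count, missing terminator...)."""


class DegenerateScaleError(ValueError):
    """A constant scale cannot be normalized (sigma = 0)."""


class UndefinedAUCError(ValueError):
    """AUC is undefined when only one class is present."""


@dataclass
class PropertyScale:
    """One AAindex1 entry.

    ``raw_values`` and ``normalized_values`` are length-20 arrays in
    :data:`CANONICAL_AA_ORDER`.  ``normalized_values`` is ``None`` for
    incomplete entries (any "NA" in the record).
    """

    accession: str
    description: str
    raw_values: np.ndarray
    normalized_values: np.ndarray | None = None
    complete: bool = True

    def value_for(self, residue: str) -> float:
        """Normalized value for a one-letter residue code.

        Non-standard residues (B, Z, X, U, ...) map to 0.0 — the mean of
        the normalized scale — as a neutral imputation.
        """
        idx = _AA_TO_INDEX.get(residue)
        if idx is None:
            logger.debug("non-standard residue %r imputed as 0.0 for %s", residue, self.accession)
            return 0.0
        if self.normalized_values is None:
            raise ValueError(f"scale {self.accession} is incomplete and not normalized")
        return float(self.normalized_values[idx])

    def values_for_sequence(self, residues: Iterable[str]) -> np.ndarray:
        return np.array([self.value_for(r) for r in residues], dtype=float)


@dataclass
class PropertyRanking:
    """Scales ordered by descending (optionally folded) AUC."""

    entries: list[tuple[str, float]]
    dataset_tag: str = ""

    @property
    def accessions(self) -> list[str]:
        return [a for a, _ in self.entries]

    def top(self, k: int) -> list[str]:
        return self.accessions[:k]


def normalize_scale(raw_values: Sequence[float]) -> np.ndarray:
    """Z-normalize a 20-value scale to zero mean, unit population std.

    The population standard deviation (denominator 20, not 19) is used.

    Raises
    ------
    DegenerateScaleError
        If all 20 values are identical (sigma = 0).
    """
    raw = np.asarray(raw_values, dtype=float)
    if raw.shape != (20,):
        raise ValueError(f"expected 20 values, got shape {raw.shape}")
    mu = raw.mean()
    sigma = raw.std(ddof=0)
    if sigma == 0.0:
        raise DegenerateScaleError("constant scale cannot be normalized (sigma = 0)")
    return (raw - mu) / sigma


def _finalize_record(
    accession: str,
    description: str,
    values: list[float | None],
    line_no: int,
) -> PropertyScale:
    if len(values) != 20:
        raise AAindexParseError(
            f"record {accession!r} near line {line_no}: expected 20 values, got {len(values)}"
        )
    complete = all(v is not None for v in values)
    raw = np.array([np.nan if v is None else v for v in values], dtype=float)
    normalized = normalize_scale(raw) if complete else None
    return PropertyScale(
        accession=accession,
        description=description,
        raw_values=raw,
        normalized_values=normalized,
        complete=complete,
    )


def parse_aaindex1(stream: TextIO | str) -> list[PropertyScale]:
    """Parse an AAindex1 flat file into :class:`PropertyScale` objects.

    The AAindex1 grammar per record: an ``H`` line with the accession,
    ``D`` line(s) with the description, an ``I`` line whose header names
    amino-acid pairs (``A/L R/K ...``) followed by two rows of 10 values
    each (first row the pair firsts A..I, second row the seconds L..V),
    terminated by ``//``.  ``NA`` marks a missing value; such entries are
    returned with ``complete=False`` and no normalized values.

    Values are re-mapped from the file's pair layout to
    :data:`CANONICAL_AA_ORDER` (for the standard header the two orders
    coincide, but the header is honoured, not assumed).
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    scales: list[PropertyScale] = []
    accession = ""
    description_parts: list[str] = []
    aa_order: list[str] = []
    pending_values: list[float | None] = []
    in_record = False
    in_values = False

    def reset() -> None:
        nonlocal accession, description_parts, aa_order, pending_values, in_record, in_values
        accession = ""
        description_parts = []
        aa_order = []
        pending_values = []
        in_record = False
        in_values = False

    for line_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("//"):
            if not in_record:
                continue
            by_aa = dict(zip(aa_order, pending_values)) if aa_order else {}
            if aa_order:
                if len(pending_values) != len(aa_order):
                    raise AAindexParseError(
                        f"record {accession!r} near line {line_no}: "
                        f"{len(pending_values)} values for {len(aa_order)} amino acids"
                    )
                ordered = [by_aa.get(aa) for aa in CANONICAL_AA_ORDER]
                missing_aa = [aa for aa in CANONICAL_AA_ORDER if aa not in by_aa]
                if missing_aa:
                    raise AAindexParseError(
                        f"record {accession!r} near line {line_no}: header lacks {missing_aa}"
                    )
            else:
                ordered = list(pending_values)
            scales.append(
                _finalize_record(accession, " ".join(description_parts), ordered, line_no)
            )
            reset()
            continue
        tag, _, rest = line.partition(" ")
        if line[0] not in " \t" and len(tag) == 1 and tag.isalpha():
            if tag == "H":
                if in_record:
                    raise AAindexParseError(
                        f"record {accession!r}: missing '//' terminator before line {line_no}"
                    )
                accession = rest.strip()
                in_record = True
                continue
            if not in_record:
                raise AAindexParseError(f"line {line_no}: field {tag!r} outside any record")
            if tag == "D":
                description_parts.append(rest.strip())
            elif tag == "I":
                pairs = rest.split()
                firsts, seconds = [], []
                for pair in pairs:
                    try:
                        a, b = pair.split("/")
                    except ValueError as exc:
                        raise AAindexParseError(
                            f"record {accession!r} line {line_no}: bad I header token {pair!r}"
                        ) from exc
                    firsts.append(a)
                    seconds.append(b)
                aa_order = firsts + seconds
                in_values = True
            # R, A, T, J, C, * lines: annotation, ignored
            continue
        # continuation / value line
        if in_values:
            for tok in line.split():
                if tok.upper() == "NA":
                    pending_values.append(None)
                else:
                    try:
                        pending_values.append(float(tok))
                    except ValueError as exc:
                        raise AAindexParseError(
                            f"record {accession!r} line {line_no}: non-numeric value {tok!r}"
                        ) from exc
        elif in_record and description_parts:
            description_parts.append(line.strip())

    if in_record:
        raise AAindexParseError(
            f"record {accession!r}: file ended without '//' terminator"
        )
    return scales


def filter_complete(scales: Iterable[PropertyScale]) -> list[PropertyScale]:
    """Drop entries with missing values (the completeness filter)."""
    return [s for s in scales if s.complete]


def scale_auc(values: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC of a scalar feature against binary labels.

    Computed as the Mann–Whitney U statistic with midrank tie handling
    (a tied positive/negative pair contributes 1/2), identical to the
    trapezoidal area under the ROC swept over all thresholds.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise UndefinedAUCError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(values, dtype=float)))


def rank_scales(
    scales: Sequence[PropertyScale],
    residues: Sequence[str],
    labels: Sequence[int],
    *,
    fold: bool = True,
    dataset_tag: str = "",
) -> PropertyRanking:
    """Rank scales by per-residue discrimination AUC, descending.

    Each sample's feature value is the scale's normalized entry for that
    residue's amino-acid type.  With ``fold=True`` (default) an AUC below
    0.5 is reported as ``1 - AUC``: a scale that separates the classes in
    either direction is equally informative.  Ties are broken by
    accession lexicographic order.
    """
    if not scales:
        raise ValueError("cannot rank an empty scale list")
    entries: list[tuple[str, float]] = []
    for scale in scales:
        auc = scale_auc(scale.values_for_sequence(residues), labels)
        if fold:
            auc = max(auc, 1.0 - auc)
        entries.append((scale.accession, auc))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return PropertyRanking(entries=entries, dataset_tag=dataset_tag)


def write_ranking_tsv(
    ranking: PropertyRanking,
    scales: Sequence[PropertyScale],
    path,
) -> None:
    """Write the ranking as TSV: accession, description, auc, rank."""
    desc = {s.accession: s.description for s in scales}
    with open(path, "w") as fh:
        fh.write("accession\tdescription\tauc\trank\n")
        for rank, (acc, auc) in enumerate(ranking.entries, start=1):
            fh.write(f"{acc}\t{desc.get(acc, '')}\t{auc:.6f}\t{rank}\n")
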