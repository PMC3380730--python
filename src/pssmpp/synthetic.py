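"""Synthetic chains, profiles, scales and planted-signal labels.

Every other module is testable offline against data from this generator,
which emulates the structure of a residue-labelled heme-protein set:

* per chain, a latent *consensus* residue at each position (uniform over
  the 20 types) stands for the evolutionarily conserved identity;
* the observed sequence mutates away from the consensus at a fixed rate,
  and the PSSM log-odds concentrate on the consensus (high value in the
  consensus column, low elsewhere, integer-rounded Gaussian noise) — so
  the profile is the less noisy channel, as it is for real proteins;
* a residue's binding probability follows a logistic link on the sum of
  the informative scales' normalized values at the consensus type, with
  slope ``effect_size`` and an intercept calibrated so the marginal
  positive rate matches ``positive_rate`` (13.5% by default, the
  binding-site fraction typical of residue-labelled heme chains).

Informative scales are drawn mutually orthogonal (Gram-Schmidt before
normalization) so each plants an independent signal; raw scale values
are rounded to 3 decimals and log-odds to integers at generation time,
which makes the flat-file round trip exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from pssmpp.aaindex import CANONICAL_AA_ORDER, PropertyScale, normalize_scale
from pssmpp.pssm import PSSMProfile, ResidueSample, write_labels, write_pssm


class CalibrationError(ValueError):
    """The marginal positive rate cannot be reached (degenerate link)."""


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    effect_size is the logistic-link slope on the informative-scale sum,
    in normalized-scale units; pssm_noise the log-odds standard deviation
    around the consensus/background means; mutation_rate the probability
    that an observed residue differs from the consensus.
    """

    n_chains: int = 60
    chain_length: tuple[int, int] = (50, 100)
    n_scales: int = 20
    n_informative: int = 2
    effect_size: float = 2.0
    positive_rate: float = 0.135
    pssm_noise: float = 1.0
    mutation_rate: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must lie in (0, 1)")
        if self.n_informative > self.n_scales:
            raise ValueError("n_informative cannot exceed n_scales")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must lie in [0, 1)")


@dataclass
class SyntheticDataset:
    config: FixtureConfig
    scales: list[PropertyScale]
    informative: list[str]
    profiles: dict[str, PSSMProfile]
    samples: list[ResidueSample]
    consensus: dict[str, np.ndarray] = field(default_factory=dict)
    intercept: float = 0.0

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)


def _orthogonalize(rows: np.ndarray) -> np.ndarray:
    """Gram-Schmidt over the leading rows (centred), keeping unit spread."""
    out = rows.astype(float).copy()
    out -= out.mean(axis=1, keepdims=True)
    for i in range(len(out)):
        for j in range(i):
            out[i] -= (out[i] @ out[j]) / (out[j] @ out[j]) * out[j]
        out[i] /= out[i].std(ddof=0)
    return out


def generate_scales(
    n_scales: int,
    n_informative: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[list[PropertyScale], list[str]]:
    """Draw ``n_scales`` synthetic 20-value scales; returns (scales, informative).

    Informative scales are mutually orthogonalized, all raw values are
    rounded to 3 decimals, and every scale is normalized.  Informative
    entries are flagged in their description and listed in the returned
    accession list.  Positions of informative scales in the output list
    are randomized.
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    rng = rng or np.random.default_rng(0)
    raw = rng.normal(size=(n_scales, 20))
    if n_informative:
        raw[:n_informative] = _orthogonalize(raw[:n_informative])
    raw = np.round(raw, 3)
    order = rng.permutation(n_scales)
    scales: list[PropertyScale] = []
    informative: list[str] = []
    for slot, src in enumerate(order):
        acc = f"SYNIDX{slot + 1:04d}"
        is_inf = src < n_informative
        if is_inf:
            informative.append(acc)
        scales.append(PropertyScale(
            accession=acc,
            description=f"Synthetic scale {slot + 1}"
                        + (" (informative)" if is_inf else " (noise)"),
            raw_values=raw[src],
            normalized_values=normalize_scale(raw[src]),
            complete=True,
        ))
    return scales, sorted(informative)


def calibrate_intercept(z_by_type: np.ndarray, effect_size: float, rate: float) -> float:
    """Intercept b0 with mean_t expit(b0 + effect_size * z_t) = rate.

    The consensus residue is uniform over the 20 types, so the marginal
    positive rate is the plain mean over types.
    """
    if not np.all(np.isfinite(z_by_type)) or not np.isfinite(effect_size):
        raise CalibrationError("non-finite link inputs")
    if effect_size == 0 or np.ptp(z_by_type) == 0:
        return float(logit(rate))

    def gap(b0: float) -> float:
        return float(expit(b0 + effect_size * z_by_type).mean() - rate)

    lo, hi = -60.0, 60.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"cannot calibrate positive rate {rate} at effect size {effect_size}"
        )
    return float(brentq(gap, lo, hi, xtol=1e-12))


def generate_dataset(config: FixtureConfig | None = None) -> SyntheticDataset:
    """Generate chains, PSSM profiles, scales and labels under ``config``.

    Deterministic under ``config.seed``; the PSSM and composition signals
    agree because both derive from the same consensus residues.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    scales, informative = generate_scales(config.n_scales, config.n_informative, rng)
    by_acc = {s.accession: s for s in scales}
    if informative:
        z_by_type = np.sum([by_acc[a].normalized_values for a in informative], axis=0)
    else:
        z_by_type = np.zeros(20)
    b0 = calibrate_intercept(z_by_type, config.effect_size, config.positive_rate)

    aa = np.array(list(CANONICAL_AA_ORDER))
    lo_len, hi_len = config.chain_length
    profiles: dict[str, PSSMProfile] = {}
    samples: list[ResidueSample] = []
    consensus: dict[str, np.ndarray] = {}
    for c in range(config.n_chains):
        chain_id = f"C{c + 1:04d}"
        L = int(rng.integers(lo_len, hi_len + 1))
        cons = rng.integers(0, 20, size=L)
        obs = cons.copy()
        mut = rng.random(L) < config.mutation_rate
        # mutate to one of the 19 other types, uniformly
        obs[mut] = (obs[mut] + rng.integers(1, 20, size=int(mut.sum()))) % 20
        p_bind = expit(b0 + config.effect_size * z_by_type[cons])
        labels = (rng.random(L) < p_bind).astype(int)

        # conserved-position profile shape: strongly positive log-odds at the
        # consensus type, strongly negative elsewhere (PSI-BLAST-like)
        log_odds = np.round(rng.normal(-4.0, config.pssm_noise, size=(L, 20)))
        log_odds[np.arange(L), cons] = np.round(rng.normal(7.0, config.pssm_noise, size=L))
        log_odds = np.clip(log_odds, -12, 12)

        sequence = "".join(aa[obs])
        profiles[chain_id] = PSSMProfile.from_log_odds(chain_id, sequence, log_odds)
        consensus[chain_id] = cons
        samples.extend(
            ResidueSample(chain_id, pos + 1, int(labels[pos])) for pos in range(L)
        )
    return SyntheticDataset(
        config=config, scales=scales, informative=informative,
        profiles=profiles, samples=samples, consensus=consensus, intercept=b0,
    )


def write_aaindex1(scales: Sequence[PropertyScale], path) -> None:
    """Write scales as an AAindex1 flat file (H/D/I records, '//' terminators)."""
    header = "    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V"
    with open(path, "w") as fh:
        for s in scales:
            fh.write(f"H {s.accession}\n")
            fh.write(f"D {s.description}\n")
            fh.write("I" + header + "\n")
            vals = [
                "     NA" if np.isnan(v) else f"{v:7.3f}"
                for v in s.raw_values
            ]
            fh.write(" " + " ".join(vals[:10]) + "\n")
            fh.write(" " + " ".join(vals[10:]) + "\n")
            fh.write("//\n")


def write_fasta(profiles: dict[str, PSSMProfile], path) -> None:
    with open(path, "w") as fh:
        for chain_id, profile in profiles.items():
            fh.write(f">{chain_id}\n")
            seq = profile.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write a self-contained dataset directory; returns the manifest.

    Layout: chains.fasta, pssm/<chain>.pssm, scales.aaindex1, labels.tsv,
    manifest.json (config, seed, informative accessions).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "pssm").mkdir(exist_ok=True)
    write_fasta(dataset.profiles, outdir / "chains.fasta")
    for chain_id, profile in dataset.profiles.items():
        write_pssm(profile, outdir / "pssm" / f"{chain_id}.pssm")
    write_aaindex1(dataset.scales, outdir / "scales.aaindex1")
    write_labels(dataset.samples, outdir / "labels.tsv")
    cfg = asdict(dataset.config)
    cfg["chain_length"] = list(cfg["chain_length"])
    manifest = {
        "config": cfg,
        "seed": dataset.config.seed,
        "informative": dataset.informative,
        "n_samples": len(dataset.samples),
        "positive_fraction": float(dataset.labels.mean()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
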