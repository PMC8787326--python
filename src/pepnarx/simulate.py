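"""Synthetic peptide-activity datasets with the structure of real screens.

The generator emulates the statistical shape of a curated antihypertensive
peptide panel: short peptides (mass on dipeptides and tripeptides), a
right-skewed, long-tailed EC50 marginal, and — under the ``fbm_profile``
link — a sorted ln(EC50) series that is a monotone fractional-Brownian
profile while the code-sorted series looks like a shuffled random series.
Two further links give a classifiable regime (``monotone_code``: ln EC50 a
smooth monotone function of the ln sequence code) and a null regime
(``independent``).

Every draw is a pure function of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import SegmentScheme
from .codec import AMINO_ACIDS, PeptideRecord, encode_sequence
from .fractal import simulate_fbm

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "ground_truth"]

_LINKS = ("fbm_profile", "monotone_code", "independent")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror the verification scale of the reference protocol:
    231 peptides, all dipeptides/tripeptides, a persistent (H = 0.7)
    activity profile with ln-scale spread ~2 and observation noise 0.3.
    """

    n: int = 231
    length_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.45, 3: 0.55}
    )
    hurst: float = 0.7
    noise_sd: float = 0.3
    link: str = "fbm_profile"
    seed: int = 0
    #: target ln-scale standard deviation of the activity profile.
    profile_sd: float = 2.0
    #: effect size of the monotone_code link (ln EC50 per SD of ln code).
    code_slope: float = 2.0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.link not in _LINKS:
            raise ValueError(f"link must be one of {_LINKS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.hurst < 1):
            raise ValueError("hurst must lie in (0, 1)")
        probs = self.length_distribution
        if not probs or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("length probabilities must sum to 1")
        if any(not (2 <= L <= 20) for L in probs):
            raise ValueError("peptide lengths must lie in 2..20")
        capacity = sum(len(AMINO_ACIDS) ** L for L, p in probs.items() if p > 0)
        if self.n > capacity:
            raise ValueError(
                f"cannot draw {self.n} distinct sequences from {capacity} available"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless activities and derived truths for a generated dataset."""

    spec: SyntheticSpec
    true_ln_ec50: np.ndarray
    #: the generating FBM path (unsorted), fbm_profile link only.
    fbm_path: np.ndarray | None
    labels_two: np.ndarray
    labels_three: np.ndarray | None


def _draw_sequences(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    lengths = sorted(L for L, p in spec.length_distribution.items() if p > 0)
    probs = np.array([spec.length_distribution[L] for L in lengths])
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < spec.n:
        L = int(rng.choice(lengths, p=probs))
        s = "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=L))
        if s not in seqs:
            seqs.add(s)
            out.append(s)
    return out


def _true_activities(
    spec: SyntheticSpec, sequences: list[str], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None]:
    n = spec.n
    if spec.link == "fbm_profile":
        # per-step scale chosen so the path spread is ~profile_sd overall
        scale = spec.profile_sd / n**spec.hurst
        path_seed = int(rng.integers(0, 2**31 - 1))
        path = simulate_fbm(spec.hurst, n, seed=path_seed, scale=scale).values
        true_ln = rng.permutation(path)
        return true_ln, path
    if spec.link == "monotone_code":
        log_codes = np.array([encode_sequence(s).log_code for s in sequences])
        z = (log_codes - log_codes.mean()) / max(log_codes.std(), 1e-12)
        return spec.code_slope * z, None
    # independent: activity carries no sequence information at all
    return rng.normal(0.0, spec.profile_sd, size=n), None


def _build(spec: SyntheticSpec) -> tuple[list[PeptideRecord], GroundTruth]:
    rng = np.random.default_rng(spec.seed)
    sequences = _draw_sequences(spec, rng)
    true_ln, path = _true_activities(spec, sequences, rng)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else 0.0
    observed_ln = true_ln + noise
    width = len(str(spec.n))
    records = [
        PeptideRecord(id=f"pep{i + 1:0{width}d}", sequence=s, ec50=float(np.exp(v)))
        for i, (s, v) in enumerate(zip(sequences, observed_ln))
    ]
    labels_two = SegmentScheme.two_class(true_ln).assign(true_ln).astype(int)
    try:
        labels_three = SegmentScheme.three_class(true_ln).assign(true_ln).astype(int)
    except ValueError:
        labels_three = None
    truth = GroundTruth(
        spec=spec,
        true_ln_ec50=true_ln,
        fbm_path=path,
        labels_two=labels_two,
        labels_three=labels_three,
    )
    return records, truth


def generate(spec: SyntheticSpec) -> list[PeptideRecord]:
    """Generate a synthetic peptide-activity dataset (seed-deterministic)."""
    records, _ = _build(spec)
    return records


def ground_truth(spec: SyntheticSpec, records: list[PeptideRecord]) -> GroundTruth:
    """Noiseless ln EC50, generating path and true segment labels.

    ``records`` must be exactly the output of :func:`generate` for this
    spec; the pairing is regenerated and verified.
    """
    regenerated, truth = _build(spec)
    if len(regenerated) != len(records) or any(
        a.id != b.id or a.sequence != b.sequence or not np.isclose(a.ec50, b.ec50)
        for a, b in zip(regenerated, records)
    ):
        raise ValueError("records do not match this spec/seed")
    return truth
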