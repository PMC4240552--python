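"""Position-specific scoring profiles with empirical E-value calibration.

The builtin backend represents each seed group by a log-odds profile over
its alignment's match columns (columns with at most 50% gaps).  Unassigned
sequences are scored by local (Smith-Waterman) alignment against the
profile with affine gap penalties; statistical significance comes from a
Gumbel null distribution fitted to shuffled decoy sequences, giving
E-values on the scale of the current database size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .align import GAP, Msa
from .model import MetaParams, ProteinRef, ProteinSequence, ValidationError

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
AA_INDEX["X"] = 20
N_SYMBOLS = 21

# Robinson & Robinson amino-acid background frequencies, renormalized.
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}
ROBINSON_BACKGROUND = np.array([_RR[a] for a in AA_ORDER], dtype=float)
ROBINSON_BACKGROUND /= ROBINSON_BACKGROUND.sum()

EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class Calibration:
    """Gumbel null parameters plus the effective database size."""

    mu: float
    lam: float
    database_size: int


@dataclass
class ProfileModel:
    """Log-odds profile (bits) over match columns of a seed alignment."""

    group_id: str
    match_scores: np.ndarray  # (L, 21) bits; column 20 is X (score 0)
    background: np.ndarray  # (20,) frequencies summing to 1
    gap_open: float
    gap_extend: float
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != N_SYMBOLS:
            raise ValidationError("match_scores must be (L, 21)")
        if self.match_scores.shape[0] < 1:
            raise ValidationError("profile must have at least one match column")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValidationError("background frequencies must sum to 1")
        if self.calibration is not None and self.calibration.lam <= 0:
            raise ValidationError("calibration lambda must be positive")

    @property
    def length(self) -> int:
        return int(self.match_scores.shape[0])

    def evalue(self, score: float) -> float:
        """Expected number of decoys scoring >= ``score``: D * P(S >= s)."""
        if self.calibration is None:
            raise ValidationError(f"profile {self.group_id} is not calibrated")
        c = self.calibration
        z = -c.lam * (score - c.mu)
        if z > 700.0:  # P(S >= s) is 1 to machine precision
            return float(c.database_size)
        return float(c.database_size) * -math.expm1(-math.exp(z))


@dataclass(frozen=True)
class ProfileHit:
    """One sequence-vs-profile comparison."""

    protein: ProteinRef
    group_id: str
    raw_score: float
    evalue: float
    seq_coverage: float
    profile_coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.seq_coverage <= 1.0 + 1e-12):
            raise ValidationError("seq_coverage outside [0, 1]")
        if not (0.0 <= self.profile_coverage <= 1.0 + 1e-12):
            raise ValidationError("profile_coverage outside [0, 1]")

    @property
    def min_coverage(self) -> float:
        return min(self.seq_coverage, self.profile_coverage)


def henikoff_weights(rows: list[str]) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff), sum 1.

    Each column contributes 1/(r*s) to every sequence showing one of its r
    distinct symbols, s being that symbol's multiplicity; gaps count as a
    symbol of their own.
    """
    n = len(rows)
    weights = np.zeros(n)
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for k, c in enumerate(col):
            weights[k] += 1.0 / (r * counts[c])
    total = weights.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return weights / total


def build_profile(
    msa: Msa,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    gap_open: float = 5.5,
    gap_extend: float = 0.5,
    group_id: str = "profile",
) -> ProfileModel:
    """Build a log-odds profile from an alignment.

    Columns with more than 50% gaps are excluded from the match states.
    Observed per-column frequencies use Henikoff sequence weights and are
    blended with the background by ``pseudocount`` total prior mass:
    f = (n*f_obs + pseudocount*bg) / (n + pseudocount), so with the default
    of 1.0 the background carries weight 1/2 at one sequence and decays as
    the sequence count grows.  Match score = log2(f / bg); X scores 0.
    """
    if background is None:
        background = ROBINSON_BACKGROUND
    background = np.asarray(background, dtype=float)
    if abs(float(background.sum()) - 1.0) > 1e-9:
        raise ValidationError("background frequencies must sum to 1")

    rows = [aligned for _ref, aligned in msa.rows]
    n_rows = len(rows)
    weights = henikoff_weights(rows)

    match_cols = [
        c
        for c in range(msa.column_count)
        if sum(row[c] == GAP for row in rows) * 2 <= n_rows
    ]
    if not match_cols:
        raise ValidationError("every column exceeds 50% gaps; no match states")

    scores = np.zeros((len(match_cols), N_SYMBOLS))
    for out_c, c in enumerate(match_cols):
        freq = np.zeros(20)
        used = 0.0
        for k, row in enumerate(rows):
            ch = row[c]
            if ch == GAP:
                continue
            if ch == "X":
                # an unknown residue is spread over the background
                freq += weights[k] * background
            else:
                freq[AA_INDEX[ch]] += weights[k]
            used += weights[k]
        if used > 0:
            freq /= used
        f = (n_rows * freq + pseudocount * background) / (n_rows + pseudocount)
        with np.errstate(divide="ignore"):
            scores[out_c, :20] = np.where(
                f > 0, np.log2(np.maximum(f, 1e-300) / background), -20.0
            )
        scores[out_c, 20] = 0.0
    return ProfileModel(
        group_id=group_id,
        match_scores=scores,
        background=background,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def encode_sequence(residues: str) -> np.ndarray:
    return np.fromiter(
        (AA_INDEX[c] for c in residues), dtype=np.int64, count=len(residues)
    )


@njit(cache=True)
def _sw_affine(scores, seq, gap_open, gap_extend):  # pragma: no cover - numba
    """Local affine-gap alignment of an encoded sequence against a profile.

    Returns (best score, profile span start/end, sequence span start/end),
    spans as 0-based inclusive column/position indices (-1s when the best
    score is 0).  Start coordinates propagate through the DP so no explicit
    traceback is needed; ties prefer diagonal, then gap-in-profile, then
    gap-in-sequence.
    """
    L = scores.shape[0]
    M = seq.shape[0]
    NEG = -1e30
    # state matrices over (profile col + 1, seq pos + 1)
    H = np.zeros((L + 1, M + 1))
    E = np.full((L + 1, M + 1), NEG)  # gap in sequence (consume profile)
    F = np.full((L + 1, M + 1), NEG)  # gap in profile (consume sequence)
    Hi = np.full((L + 1, M + 1), -1, dtype=np.int64)
    Hj = np.full((L + 1, M + 1), -1, dtype=np.int64)
    Ei = np.full((L + 1, M + 1), -1, dtype=np.int64)
    Ej = np.full((L + 1, M + 1), -1, dtype=np.int64)
    Fi = np.full((L + 1, M + 1), -1, dtype=np.int64)
    Fj = np.full((L + 1, M + 1), -1, dtype=np.int64)

    best = 0.0
    best_i = -1
    best_j = -1
    best_si = -1
    best_sj = -1
    for i in range(1, L + 1):
        for j in range(1, M + 1):
            # E: gap in sequence, coming down a profile column
            open_score = H[i - 1, j] - gap_open
            ext_score = E[i - 1, j] - gap_extend
            if open_score >= ext_score:
                E[i, j] = open_score
                Ei[i, j] = Hi[i - 1, j]
                Ej[i, j] = Hj[i - 1, j]
            else:
                E[i, j] = ext_score
                Ei[i, j] = Ei[i - 1, j]
                Ej[i, j] = Ej[i - 1, j]
            # F: gap in profile, moving along the sequence
            open_score = H[i, j - 1] - gap_open
            ext_score = F[i, j - 1] - gap_extend
            if open_score >= ext_score:
                F[i, j] = open_score
                Fi[i, j] = Hi[i, j - 1]
                Fj[i, j] = Hj[i, j - 1]
            else:
                F[i, j] = ext_score
                Fi[i, j] = Fi[i, j - 1]
                Fj[i, j] = Fj[i, j - 1]
            # H: best of restart, diagonal, F, E (preference in that order)
            diag = H[i - 1, j - 1] + scores[i - 1, seq[j - 1]]
            di = Hi[i - 1, j - 1]
            dj = Hj[i - 1, j - 1]
            if di < 0:
                di = i - 1
                dj = j - 1
            h = diag
            hi = di
            hj = dj
            if F[i, j] > h:
                h = F[i, j]
                hi = Fi[i, j]
                hj = Fj[i, j]
            if E[i, j] > h:
                h = E[i, j]
                hi = Ei[i, j]
                hj = Ej[i, j]
            if h <= 0.0:
                h = 0.0
                hi = -1
                hj = -1
            H[i, j] = h
            Hi[i, j] = hi
            Hj[i, j] = hj
            if h > best:
                best = h
                best_i = i - 1
                best_j = j - 1
                best_si = hi
                best_sj = hj
    return best, best_si, best_i, best_sj, best_j


def score_sequence(profile: ProfileModel, seq: ProteinSequence) -> ProfileHit:
    """Score one sequence against a calibrated profile.

    Coverage is the aligned span over the full length, on both the sequence
    side and the profile side; a best local score of 0 yields 0 coverage.
    """
    if profile.calibration is None:
        raise ValidationError(f"profile {profile.group_id} is not calibrated")
    raw, si, ei, sj, ej = _sw_affine(
        profile.match_scores,
        encode_sequence(seq.residues),
        profile.gap_open,
        profile.gap_extend,
    )
    if raw <= 0.0 or si < 0:
        return ProfileHit(
            protein=seq.ref,
            group_id=profile.group_id,
            raw_score=0.0,
            evalue=float(profile.calibration.database_size),
            seq_coverage=0.0,
            profile_coverage=0.0,
        )
    return ProfileHit(
        protein=seq.ref,
        group_id=profile.group_id,
        raw_score=float(raw),
        evalue=profile.evalue(float(raw)),
        seq_coverage=(ej - sj + 1) / len(seq),
        profile_coverage=(ei - si + 1) / profile.length,
    )


def raw_local_score(profile: ProfileModel, residues: str) -> float:
    """Raw local-alignment score, usable before calibration."""
    raw, *_ = _sw_affine(
        profile.match_scores,
        encode_sequence(residues),
        profile.gap_open,
        profile.gap_extend,
    )
    return float(raw)


def fit_gumbel_moments(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: lam = pi/(sd*sqrt(6)), mu = mean - gamma/lam."""
    scores = np.asarray(scores, dtype=float)
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        raise ValidationError("decoy scores have zero variance; cannot calibrate")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = float(scores.mean()) - EULER_GAMMA / lam
    return mu, lam


def calibrate_profile(
    profile: ProfileModel,
    decoy_pool: list[ProteinSequence],
    n_decoys: int,
    rng: np.random.Generator,
    database_size: int | None = None,
) -> ProfileModel:
    """Fit the profile's Gumbel null from shuffled decoy sequences.

    Decoys are drawn with replacement from ``decoy_pool`` and residue-
    shuffled, which preserves composition and length while destroying
    positional signal.  ``database_size`` defaults to the pool size.
    """
    if n_decoys < 50:
        raise ValidationError("n_decoys must be >= 50")
    if not decoy_pool:
        raise ValidationError("decoy pool is empty")
    scores = np.empty(n_decoys)
    for k in range(n_decoys):
        src = decoy_pool[int(rng.integers(len(decoy_pool)))]
        shuffled = "".join(
            src.residues[i] for i in rng.permutation(len(src.residues))
        )
        scores[k] = raw_local_score(profile, shuffled)
    mu, lam = fit_gumbel_moments(scores)
    D = database_size if database_size is not None else len(decoy_pool)
    return replace(profile, calibration=Calibration(mu=mu, lam=lam, database_size=D))


def assign_unassigned(
    profiles: list[ProfileModel],
    unassigned: list[ProteinSequence],
    params: MetaParams,
) -> dict[ProteinRef, str]:
    """Assign each unassigned protein to at most one profile.

    A profile is eligible iff its E-value is strictly below the threshold
    and both coverages reach ``min_coverage``.  Among eligible profiles the
    lowest E-value wins, then the highest min-coverage, then the smallest
    group id.  Profiles are never updated within a pass.
    """
    out: dict[ProteinRef, str] = {}
    for seq in sorted(unassigned, key=lambda s: s.ref):
        best: tuple[float, float, str] | None = None
        for profile in profiles:
            hit = score_sequence(profile, seq)
            if hit.evalue < params.evalue_threshold and (
                hit.min_coverage >= params.min_coverage
            ):
                key = (hit.evalue, -hit.min_coverage, profile.group_id)
                if best is None or key < best:
                    best = key
        if best is not None:
            out[seq.ref] = best[2]
    return out
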