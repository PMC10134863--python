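"""Per-proteome composition traits: IVYWREL/OGT, residue groups, and pI.

Two families of reverse-ecology statistics are computed from a proteome:

* **Thermal proxies.**  The pooled frequency of the seven residues
  Ile, Val, Tyr, Trp, Arg, Glu, Leu (the *IVYWREL fraction*, ``F``) rises
  approximately linearly with the optimal growth temperature of prokaryotes,
  so ``OGT ≈ slope·F + intercept`` with published regression constants
  (defaults: slope 937.0 °C, intercept −335.0 °C).  The combined R+E
  fraction and the proline fraction are secondary thermostability proxies.

* **pH proxies.**  Each protein's isoelectric point (pI) is the pH at which
  its Henderson–Hasselbalch net charge is zero.  Proteome pI distributions
  are typically bimodal (an acidic and a basic mode with a depleted
  near-neutral trough); the trough location partitions proteins into acidic
  and basic classes, and the signed class imbalance is the *pI bias*
  (positive when basic proteins outnumber acidic ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .proteome import CANONICAL_AA, Proteome, sanitize

__all__ = [
    "PkaSet", "IPC_PROTEIN", "EMBOSS", "PKA_SETS",
    "residue_frequencies", "ivywrel_fraction", "ogt_from_ivywrel",
    "group_fraction", "net_charge", "protein_pi", "proteome_pi",
    "pi_trough", "TroughResult", "pi_bias", "PiProfile",
    "CompositionTraits", "composition_traits", "pi_profile",
    "IVYWREL", "OGT_SLOPE_DEFAULT", "OGT_INTERCEPT_DEFAULT",
]

IVYWREL = frozenset("IVYWREL")

# Published fit of OGT (°C) on the IVYWREL fraction for prokaryotes.
OGT_SLOPE_DEFAULT = 937.0
OGT_INTERCEPT_DEFAULT = -335.0


@dataclass(frozen=True)
class PkaSet:
    """A named table of dissociation constants for the ionizable groups.

    ``side_chain`` maps residue letters (subset of D, E, C, Y, H, K, R) to
    pKa values; ``polarity`` says whether each group (residue letter or the
    pseudo-residues ``Nterm``/``Cterm``) titrates as an acid or a base.
    """

    name: str
    n_term: float
    c_term: float
    side_chain: dict[str, float]
    polarity: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        default_polarity = {
            "Nterm": "basic", "Cterm": "acidic",
            "D": "acidic", "E": "acidic", "C": "acidic", "Y": "acidic",
            "H": "basic", "K": "basic", "R": "basic",
        }
        pol = dict(default_polarity)
        pol.update(self.polarity)
        object.__setattr__(self, "polarity", pol)
        for group, pka in self.all_pka().items():
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa of {group} out of (0, 14): {pka}")
            if group not in pol:
                raise ValueError(f"no polarity defined for group {group}")

    def all_pka(self) -> dict[str, float]:
        out = {"Nterm": self.n_term, "Cterm": self.c_term}
        out.update(self.side_chain)
        return out


# Values from the IPC isoelectric-point calculator's protein-optimised set.
IPC_PROTEIN = PkaSet(
    name="ipc",
    n_term=9.094,
    c_term=2.869,
    side_chain={"C": 7.555, "D": 3.872, "E": 4.412,
                "H": 5.637, "K": 9.052, "R": 11.84, "Y": 10.85},
)

# Classic EMBOSS ``iep`` defaults, kept for comparison runs.
EMBOSS = PkaSet(
    name="emboss",
    n_term=8.6,
    c_term=3.6,
    side_chain={"C": 8.5, "D": 3.9, "E": 4.1,
                "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1},
)

PKA_SETS: dict[str, PkaSet] = {"ipc": IPC_PROTEIN, "emboss": EMBOSS}


# ---------------------------------------------------------------------------
# Composition traits
# ---------------------------------------------------------------------------

def residue_frequencies(proteome: Proteome) -> dict[str, float]:
    """Pooled residue frequencies over the whole proteome.

    Ambiguity codes (B, J, O, U, X, Z) and stops are excluded from both
    numerator and denominator, so frequencies sum to one over the canonical
    residues actually counted.
    """
    counts = {aa: 0 for aa in CANONICAL_AA}
    dropped = 0
    for _, seq in proteome:
        for ch in seq:
            if ch in counts:
                counts[ch] += 1
            else:
                dropped += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(
            f"proteome {proteome.genome_id!r} contains no canonical residues"
        )
    if dropped:
        warnings.warn(
            f"{proteome.genome_id}: dropped {dropped} non-canonical residues"
        )
    return {aa: n / total for aa, n in counts.items()}


def ivywrel_fraction(proteome: Proteome) -> float:
    """Summed frequency of I, V, Y, W, R, E, L over the proteome."""
    freqs = residue_frequencies(proteome)
    return sum(freqs[aa] for aa in IVYWREL)


def ogt_from_ivywrel(f_ivywrel: float,
                     slope: float = OGT_SLOPE_DEFAULT,
                     intercept: float = OGT_INTERCEPT_DEFAULT) -> float:
    """Linear OGT estimate (°C) from the IVYWREL fraction."""
    if not 0.0 <= f_ivywrel <= 1.0:
        raise ValueError(f"IVYWREL fraction out of [0, 1]: {f_ivywrel}")
    return slope * f_ivywrel + intercept


def group_fraction(proteome: Proteome, residues: set[str] | frozenset[str] | str) -> float:
    """Summed frequency of an arbitrary residue group (e.g. {R, E} or {P})."""
    residues = frozenset(residues)
    if not residues:
        raise ValueError("empty residue set")
    unknown = residues - frozenset(CANONICAL_AA)
    if unknown:
        raise ValueError(f"non-canonical residues requested: {sorted(unknown)}")
    freqs = residue_frequencies(proteome)
    return sum(freqs[aa] for aa in residues)


# ---------------------------------------------------------------------------
# Net charge and isoelectric point
# ---------------------------------------------------------------------------

def _group_counts(sequence: str, pka: PkaSet, count_termini: bool = True) -> dict[str, int]:
    seq = sanitize(sequence)
    counts = {g: 0 for g in pka.all_pka()}
    for ch in seq:
        if ch in pka.side_chain:
            counts[ch] += 1
    if count_termini and seq:
        counts["Nterm"] = 1
        counts["Cterm"] = 1
    return counts


def _charge_from_counts(counts_matrix: np.ndarray, pkas: np.ndarray,
                        signs: np.ndarray, ph: np.ndarray) -> np.ndarray:
    """Vectorised Henderson–Hasselbalch net charge.

    ``counts_matrix``: (n_proteins, n_groups); ``ph`` broadcastable against
    proteins.  Basic groups contribute ``+n/(1+10^(pH−pKa))``, acidic groups
    ``−n/(1+10^(pKa−pH))``.
    """
    ph = np.asarray(ph, dtype=float)
    # delta has shape (..., n_groups)
    delta = np.where(signs > 0, ph[..., None] - pkas, pkas - ph[..., None])
    frac = 1.0 / (1.0 + 10.0 ** delta)
    return np.sum(signs * counts_matrix * frac, axis=-1)


def _pka_arrays(pka: PkaSet) -> tuple[list[str], np.ndarray, np.ndarray]:
    groups = sorted(pka.all_pka())
    pkas = np.array([pka.all_pka()[g] for g in groups])
    signs = np.array([1.0 if pka.polarity[g] == "basic" else -1.0 for g in groups])
    return groups, pkas, signs


def net_charge(sequence: str, ph: float, pka: PkaSet = IPC_PROTEIN,
               count_termini: bool = True) -> float:
    """Net charge of a protein at a given pH under a pKa table.

    Strictly decreasing in pH; unknown residues contribute nothing.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH out of [0, 14]: {ph}")
    counts = _group_counts(sequence, pka, count_termini)
    groups, pkas, signs = _pka_arrays(pka)
    vec = np.array([counts[g] for g in groups], dtype=float)
    return float(_charge_from_counts(vec, pkas, signs, np.array(ph)))


def _bisect_pi(counts_matrix: np.ndarray, pkas: np.ndarray, signs: np.ndarray,
               tol: float = 1e-4, max_iter: int = 100) -> np.ndarray:
    """Vectorised bisection of Q(pH) = 0 on [0, 14] for many proteins at once.

    Q is strictly decreasing, so the root is unique when it exists.  Rows
    with no ionizable groups return NaN.
    """
    n = counts_matrix.shape[0]
    lo = np.zeros(n)
    hi = np.full(n, 14.0)
    has_groups = counts_matrix.sum(axis=1) > 0
    q_lo = _charge_from_counts(counts_matrix, pkas, signs, lo)
    q_hi = _charge_from_counts(counts_matrix, pkas, signs, hi)
    # clamp monotone curves that never cross zero to the nearer boundary
    all_neg = q_lo <= 0
    all_pos = q_hi >= 0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q = _charge_from_counts(counts_matrix, pkas, signs, mid)
        go_right = q > 0
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
        if np.all((hi - lo) < 1e-12):
            break
    out = 0.5 * (lo + hi)
    out[all_neg] = 0.0
    out[all_pos] = 14.0
    out[~has_groups] = np.nan
    return out


def protein_pi(sequence: str, pka: PkaSet = IPC_PROTEIN, tol: float = 1e-4,
               count_termini: bool = True) -> float:
    """Isoelectric point of one protein by bisection of the charge curve.

    ``tol`` bounds both |Q(pI)| and the bracketing interval; the charge
    curve is strictly monotone so bisection always converges.
    """
    counts = _group_counts(sequence, pka, count_termini)
    if sum(counts.values()) == 0:
        raise ValueError("sequence has no ionizable groups; pI undefined")
    groups, pkas, signs = _pka_arrays(pka)
    vec = np.array([[counts[g] for g in groups]], dtype=float)
    return float(_bisect_pi(vec, pkas, signs, tol=tol)[0])


def proteome_pi(proteome: Proteome, pka: PkaSet = IPC_PROTEIN,
                tol: float = 1e-4) -> tuple[np.ndarray, float]:
    """Per-protein pI values and their arithmetic mean for one proteome.

    Proteins without ionizable groups are excluded from both the list and
    the mean (with a warning).
    """
    groups, pkas, signs = _pka_arrays(pka)
    mat = np.array(
        [[_group_counts(seq, pka)[g] for g in groups] for _, seq in proteome],
        dtype=float,
    ).reshape(len(proteome), len(groups))
    pis = _bisect_pi(mat, pkas, signs, tol=tol)
    n_undefined = int(np.isnan(pis).sum())
    if n_undefined:
        warnings.warn(
            f"{proteome.genome_id}: {n_undefined} proteins with undefined pI excluded"
        )
        pis = pis[~np.isnan(pis)]
    if pis.size == 0:
        raise ValueError(f"proteome {proteome.genome_id!r} has no defined pI values")
    return pis, float(np.mean(pis))


# ---------------------------------------------------------------------------
# Trough detection and pI bias
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TroughResult:
    """Breakpoint between the acidic and basic pI modes.

    ``unimodal`` flags the fallback (breakpoint fixed at ``fallback``) used
    when the kernel density has fewer than two modes or too few proteins.
    """

    breakpoint: float
    unimodal: bool


def pi_trough(pi_values, grid_step: float = 0.01,
              search_window: tuple[float, float] = (4.0, 10.0),
              fallback: float = 7.0, min_n: int = 10) -> TroughResult:
    """Locate the density trough separating acidic and basic proteins.

    A Gaussian kernel density (Silverman bandwidth) is evaluated on a fixed
    pH grid over [0, 14]; the breakpoint is the grid point of minimum
    density between the two highest local maxima, clipped to
    ``search_window``.  Unimodal densities (and samples below ``min_n``)
    fall back to a fixed neutral breakpoint.
    """
    pis = np.asarray(list(pi_values), dtype=float)
    if pis.size == 0:
        raise ValueError("empty pI list")
    if pis.size < min_n or np.allclose(pis, pis[0]):
        return TroughResult(fallback, True)
    grid = np.arange(0.0, 14.0 + grid_step / 2, grid_step)
    density = gaussian_kde(pis, bw_method="silverman")(grid)
    # prominence filter suppresses KDE ripples that are not real modes
    peaks, _ = find_peaks(density, prominence=0.05 * density.max())
    if peaks.size < 2:
        return TroughResult(fallback, True)
    top_two = peaks[np.argsort(density[peaks])[-2:]]
    left, right = sorted(grid[top_two])
    lo = max(left, search_window[0])
    hi = min(right, search_window[1])
    if lo >= hi:
        return TroughResult(fallback, True)
    mask = (grid >= lo) & (grid <= hi)
    idx = np.flatnonzero(mask)[np.argmin(density[mask])]
    return TroughResult(float(grid[idx]), False)


def pi_bias(pi_values, breakpoint: float) -> tuple[float, int, int]:
    """Signed basic-vs-acidic imbalance of a proteome's pI values.

    Returns ``(bias, n_acidic, n_basic)`` with
    ``bias = (n_basic − n_acidic) / (n_basic + n_acidic)``; proteins exactly
    at the breakpoint count as acidic.  Positive bias means basic proteins
    predominate.
    """
    if not 0.0 < breakpoint < 14.0:
        raise ValueError(f"breakpoint out of (0, 14): {breakpoint}")
    pis = np.asarray(list(pi_values), dtype=float)
    if pis.size == 0:
        raise ValueError("empty pI list")
    n_acidic = int(np.sum(pis <= breakpoint))
    n_basic = int(np.sum(pis > breakpoint))
    bias = (n_basic - n_acidic) / (n_basic + n_acidic)
    return bias, n_acidic, n_basic


# ---------------------------------------------------------------------------
# Aggregate records
# ---------------------------------------------------------------------------

@dataclass
class CompositionTraits:
    genome_id: str
    frequencies: dict[str, float]
    f_ivywrel: float
    ogt_ivywrel: float
    f_re: float
    f_p: float


@dataclass
class PiProfile:
    genome_id: str
    pi_values: np.ndarray
    average_pi: float
    breakpoint: float
    unimodal: bool
    pi_bias: float
    n_acidic: int
    n_basic: int


def composition_traits(proteome: Proteome,
                       slope: float = OGT_SLOPE_DEFAULT,
                       intercept: float = OGT_INTERCEPT_DEFAULT) -> CompositionTraits:
    """All composition-derived traits of one proteome in a single pass."""
    freqs = residue_frequencies(proteome)
    f = sum(freqs[aa] for aa in IVYWREL)
    return CompositionTraits(
        genome_id=proteome.genome_id,
        frequencies=freqs,
        f_ivywrel=f,
        ogt_ivywrel=ogt_from_ivywrel(f, slope, intercept),
        f_re=freqs["R"] + freqs["E"],
        f_p=freqs["P"],
    )


def pi_profile(proteome: Proteome, pka: PkaSet = IPC_PROTEIN) -> PiProfile:
    """Per-proteome pI distribution summary (mean, trough, bias)."""
    pis, avg = proteome_pi(proteome, pka)
    trough = pi_trough(pis)
    bias, n_acidic, n_basic = pi_bias(pis, trough.breakpoint)
    return PiProfile(
        genome_id=proteome.genome_id,
        pi_values=pis,
        average_pi=avg,
        breakpoint=trough.breakpoint,
        unimodal=trough.unimodal,
        pi_bias=bias,
        n_acidic=n_acidic,
        n_basic=n_basic,
    )
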