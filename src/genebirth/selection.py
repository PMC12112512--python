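"""Pairwise Ka/Ks estimation and the negative-selection likelihood-ratio test.

Two independent estimators are provided:

* :func:`ng86_kaks` — Nei-Gojobori (1986) pathway counting with equal-weight
  multi-hit paths and Jukes-Cantor correction, used as a fast counting
  cross-check;
* :func:`ml_pairwise_omega` — maximum likelihood under a 61-state codon
  substitution model (Goldman-Yang style: substitution rate proportional to
  the target codon's equilibrium frequency, multiplied by kappa for
  transitions and by omega for nonsynonymous changes; multi-nucleotide
  changes have rate zero), maximising over divergence t (and omega and kappa
  when free).

The selection test compares the free-omega model against omega fixed at 0.5
with a chi-square(df=1) LRT; a pair is called under negative selection when
omega_hat < 0.5 and p < 0.05.  Pairs with Ka > 0.5, Ks > 5, or Ks above the
upper Tukey fence (Q3 + 1.5 IQR) of the remaining Ks distribution are
excluded before summary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from genebirth.io_formats import ValidationError
from genebirth._util import round_half_up

NT = "TCAG"
STOP_CODONS = {"TAA", "TAG", "TGA"}
ALL_CODONS = ["".join(c) for c in itertools.product(NT, repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61 under the standard code

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


CODON_AA = {c: _translate(c) for c in SENSE_CODONS}

# single-nucleotide neighbour table: (i, j, position, is_transition, is_synonymous)
_NEIGHBOURS: list[tuple[int, int, int, bool, bool]] = []
for _i, _ci in enumerate(SENSE_CODONS):
    for _pos in range(3):
        for _nt in NT:
            if _nt == _ci[_pos]:
                continue
            _cj = _ci[:_pos] + _nt + _ci[_pos + 1:]
            if _cj in STOP_CODONS:
                continue
            _NEIGHBOURS.append((
                _i, CODON_INDEX[_cj], _pos,
                (_ci[_pos], _nt) in _TRANSITIONS,
                CODON_AA[_ci] == CODON_AA[_cj],
            ))

_NEI_I = np.array([n[0] for n in _NEIGHBOURS])
_NEI_J = np.array([n[1] for n in _NEIGHBOURS])
_NEI_TS = np.array([n[3] for n in _NEIGHBOURS])
_NEI_SYN = np.array([n[4] for n in _NEIGHBOURS])


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """A pair of gap-aligned CDS strings with codon-structured gaps."""

    seq_a: str
    seq_b: str
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        if len(a) != len(b):
            raise ValidationError("aligned CDS lengths differ")
        if len(a) % 3 != 0:
            raise ValidationError("aligned length not divisible by 3")
        for seq in (a, b):
            for k in range(0, len(seq), 3):
                cod = seq[k:k + 3]
                if "-" in cod and cod != "---":
                    raise ValidationError(f"gap not in 3-nt block at column {k + 1}")
        for ca, cb in self.codon_pairs():
            if ca in STOP_CODONS or cb in STOP_CODONS:
                raise ValidationError("internal stop codon in ungapped column")
        self.seq_a, self.seq_b = a, b

    @property
    def n_codon_columns(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Codon pairs at ungapped columns."""
        out = []
        for k in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[k:k + 3], self.seq_b[k:k + 3]
            if "-" not in ca and "-" not in cb:
                out.append((ca, cb))
        return out

    @property
    def n_ungapped_columns(self) -> int:
        return len(self.codon_pairs())


def back_translate_alignment(protein_a: str, protein_b: str,
                             cds_a: str, cds_b: str,
                             id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Thread CDS codons onto a gapped protein alignment (PAL2NAL-style).

    Each CDS must translate, residue for residue, to its ungapped protein; a
    terminal stop codon on the CDS is trimmed first.  A protein gap becomes
    a 3-nt gap.
    """
    rows = []
    for prot, cds, name in ((protein_a, cds_a, id_a), (protein_b, cds_b, id_b)):
        cds = cds.upper().replace("U", "T")
        if len(cds) % 3 != 0:
            raise ValidationError(f"{name}: CDS length {len(cds)} not divisible by 3")
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        ungapped = prot.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValidationError(
                f"{name}: CDS ({len(cds)} nt) does not match protein length {len(ungapped)} aa")
        k = 0
        row = []
        for res in prot:
            if res == "-":
                row.append("---")
                continue
            codon = cds[3 * k:3 * k + 3]
            aa = CODON_AA.get(codon)
            if aa is None:
                raise ValidationError(f"{name}: stop/invalid codon {codon} at residue {k + 1}")
            if aa != res.upper():
                raise ValidationError(
                    f"{name}: translation mismatch at residue {k + 1}: "
                    f"codon {codon} -> {aa}, protein has {res}")
            row.append(codon)
            k += 1
        rows.append("".join(row))
    return CodonAlignment(rows[0], rows[1], id_a, id_b)


def align_protein_pair(prot_a: str, prot_b: str) -> tuple[str, str]:
    """Global protein alignment with BLOSUM62 (open -10, extend -0.5)."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(prot_a, prot_b)[0]
    return str(aln[0]), str(aln[1])


def align_cds_pair(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Translate, align at the protein level, then back-translate to codons."""
    def _prot(cds, name):
        cds = cds.upper().replace("U", "T")
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        if len(cds) % 3 != 0:
            raise ValidationError(f"{name}: CDS length not divisible by 3")
        return str(Seq(cds).translate())
    pa, pb = _prot(cds_a, id_a), _prot(cds_b, id_b)
    if "*" in pa or "*" in pb:
        raise ValidationError("internal stop codon in CDS")
    aa, ab = align_protein_pair(pa, pb)
    return back_translate_alignment(aa, ab, cds_a, cds_b, id_a, id_b)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _ng86_site_counts(codon: str) -> tuple[float, float]:
    """Expected synonymous/nonsynonymous sites of one codon (stops skipped)."""
    syn = 0.0
    for pos in range(3):
        for nt in NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue  # counted as nonsynonymous
            if CODON_AA[alt] == CODON_AA[codon]:
                syn += 1 / 3
    return syn, 3.0 - syn


def _ng86_diff_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average syn/nonsyn differences over equal-weight minimal pathways."""
    positions = [p for p in range(3) if ca[p] != cb[p]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = ca
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                valid = False
                break
            if CODON_AA[cur] == CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            paths.append((sd, nd))
    if not paths:  # all pathways pass through a stop: fall back to including them
        for order in itertools.permutations(positions):
            cur = ca
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in STOP_CODONS or CODON_AA.get(cur, "*") != CODON_AA.get(nxt, "*"):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass
class NG86Result:
    ka: float
    ks: float
    saturated: bool

    @property
    def omega(self) -> float:
        if self.ks <= 0 or self.saturated:
            return math.nan
        return self.ka / self.ks


def ng86_kaks(aln: CodonAlignment) -> NG86Result:
    """Nei-Gojobori (1986) Ka and Ks with Jukes-Cantor multiple-hit correction.

    Saturated proportions (p >= 3/4) leave the corresponding distance as NaN
    and flag the result instead of raising.
    """
    pairs = aln.codon_pairs()
    if not pairs:
        raise ValidationError("no ungapped codon columns")
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, na = _ng86_site_counts(ca)
        sb, nb = _ng86_site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _ng86_diff_counts(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0

    def jc(p):
        if p >= 0.75:
            return math.nan
        return -0.75 * math.log(1 - 4 * p / 3)

    ks, ka = jc(ps), jc(pn)
    return NG86Result(ka=ka, ks=ks, saturated=math.isnan(ka) or math.isnan(ks))


# ---------------------------------------------------------------------------
# GY94-style pairwise maximum likelihood
# ---------------------------------------------------------------------------

def f1x4_codon_frequencies(sequences: Sequence[str]) -> np.ndarray:
    """F1x4 equilibrium codon frequencies from the pooled nucleotide composition."""
    counts = {n: 1.0 for n in NT}  # one pseudocount per nucleotide
    for seq in sequences:
        for ch in seq.upper():
            if ch in counts:
                counts[ch] += 1
    tot = sum(counts.values())
    ntfreq = {n: counts[n] / tot for n in NT}
    pi = np.array([ntfreq[c[0]] * ntfreq[c[1]] * ntfreq[c[2]] for c in SENSE_CODONS])
    return pi / pi.sum()


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Normalised 61x61 codon rate matrix (mean rate 1 substitution/codon)."""
    Q = np.zeros((N_SENSE, N_SENSE))
    rates = pi[_NEI_J] * np.where(_NEI_TS, kappa, 1.0) * np.where(_NEI_SYN, 1.0, omega)
    Q[_NEI_I, _NEI_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise ValidationError("degenerate rate matrix")
    return Q / scale


def synonymous_flow_fraction(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Fraction of substitutions that are synonymous under the model."""
    rates = pi[_NEI_J] * np.where(_NEI_TS, kappa, 1.0) * np.where(_NEI_SYN, 1.0, omega)
    flow = pi[_NEI_I] * rates
    return float(flow[_NEI_SYN].sum() / flow.sum())


def _pattern_counts(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    counts: dict[tuple[int, int], int] = {}
    for ca, cb in aln.codon_pairs():
        key = (CODON_INDEX[ca], CODON_INDEX[cb])
        counts[key] = counts.get(key, 0) + 1
    ii = np.array([k[0] for k in counts])
    jj = np.array([k[1] for k in counts])
    nn = np.array(list(counts.values()), dtype=float)
    return ii, jj, nn


def _log_likelihood(t: float, kappa: float, omega: float, pi: np.ndarray,
                    ii: np.ndarray, jj: np.ndarray, nn: np.ndarray) -> float:
    Q = build_rate_matrix(kappa, omega, pi)
    P = linalg.expm(Q * t)
    probs = pi[ii] * np.maximum(P[ii, jj], 1e-300)
    return float((nn * np.log(probs)).sum())


T_BOUNDS = (1e-6, 50.0)
OMEGA_BOUNDS = (1e-6, 10.0)
KAPPA_BOUNDS = (0.1, 50.0)


@dataclass
class MLFit:
    lnL: float
    t_hat: float
    omega_hat: float
    kappa_hat: float
    converged: bool = True


def ml_pairwise_omega(aln: CodonAlignment, fix_omega: float | None = None,
                      kappa: float | None = None,
                      codon_freq: str = "f1x4") -> MLFit:
    """Maximise the pairwise codon-model likelihood over t (and omega, kappa).

    ``fix_omega`` pins omega (the null model of the LRT); ``kappa`` pins the
    transition/transversion rate ratio, otherwise it is estimated by joint
    profile likelihood.  Codon frequencies are F1x4 from the pair (default)
    or uniform.  Bounded multi-start L-BFGS-B, convergence tolerance 1e-8.
    """
    if codon_freq == "f1x4":
        pi = f1x4_codon_frequencies([aln.seq_a.replace("-", ""), aln.seq_b.replace("-", "")])
    elif codon_freq == "uniform":
        pi = uniform_codon_frequencies()
    else:
        raise ValidationError(f"unknown codon_freq {codon_freq!r}")
    ii, jj, nn = _pattern_counts(aln)
    if nn.sum() == 0:
        raise ValidationError("alignment has no ungapped codon columns")

    # crude starting divergence from the raw proportion of differing columns
    p_diff = float(nn[ii != jj].sum() / nn.sum())
    t0 = max(3 * p_diff / 2, 1e-4)

    free_omega = fix_omega is None
    free_kappa = kappa is None

    def unpack(x):
        k = 0
        t = math.exp(x[k]); k += 1
        om = math.exp(x[k]) if free_omega else fix_omega
        k += free_omega
        ka = math.exp(x[k]) if free_kappa else kappa
        return t, om, ka

    def neg(x):
        t, om, ka = unpack(x)
        return -_log_likelihood(t, ka, om, pi, ii, jj, nn)

    bounds = [tuple(math.log(b) for b in T_BOUNDS)]
    if free_omega:
        bounds.append(tuple(math.log(b) for b in OMEGA_BOUNDS))
    if free_kappa:
        bounds.append(tuple(math.log(b) for b in KAPPA_BOUNDS))

    starts = []
    for om0 in ([0.2, 1.0] if free_omega else [None]):
        x = [math.log(t0)]
        if free_omega:
            x.append(math.log(om0))
        if free_kappa:
            x.append(math.log(2.0))
        starts.append(x)

    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500})
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ValidationError(f"codon-model optimisation failed: {best}")
    t, om, ka = unpack(best.x)
    return MLFit(lnL=-float(best.fun), t_hat=t, omega_hat=om, kappa_hat=ka,
                 converged=any_ok)


def ml_ka_ks(fit: MLFit, pi: np.ndarray) -> tuple[float, float]:
    """Decompose an ML fit into per-site Ka and Ks (model-based site counts)."""
    rho = synonymous_flow_fraction(fit.kappa_hat, fit.omega_hat, pi)
    rho1 = synonymous_flow_fraction(fit.kappa_hat, 1.0, pi)
    ks = fit.t_hat * rho / (3 * rho1)
    ka = fit.t_hat * (1 - rho) / (3 * (1 - rho1))
    return ka, ks


def lrt_negative_selection(lnL_free: float, lnL_null: float, omega_hat: float,
                           omega_null: float = 0.5, alpha: float = 0.05,
                           tol: float = 1e-4) -> tuple[float, bool]:
    """Chi-square(df=1) LRT of free omega against omega = ``omega_null``.

    Returns (p_value, negative_selection); the call additionally requires
    omega_hat < omega_null so that a significant omega above the null is not
    misreported as constraint.
    """
    stat = 2.0 * (lnL_free - lnL_null)
    if stat < -tol:
        raise ValidationError(
            f"free log-likelihood below null beyond tolerance (2dlnL = {stat:.3g})")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return p, (omega_hat < omega_null and p < alpha)


# ---------------------------------------------------------------------------
# per-pair driver, filters, summary
# ---------------------------------------------------------------------------

REASON_KA = "ka_gt"
REASON_KS = "ks_gt"
REASON_IQR = "ks_iqr_outlier"
REASON_NONE = "none"


@dataclass
class SelectionConfig:
    kappa: float | None = None          # None: profile-likelihood estimate
    codon_freq: str = "f1x4"
    omega_null: float = 0.5
    alpha: float = 0.05
    ka_max: float = 0.5
    ks_max: float = 5.0
    iqr_multiplier: float = 1.5


@dataclass
class KaKsResult:
    id_a: str
    id_b: str
    ka: float
    ks: float
    omega: float
    lnL_free: float
    lnL_null: float
    p_value: float
    negative_selection: bool
    excluded_reason: str = REASON_NONE


def analyze_pair(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b",
                 config: SelectionConfig | None = None,
                 aln: CodonAlignment | None = None) -> KaKsResult:
    """Full single-pair analysis: align, fit free and null models, test."""
    config = config or SelectionConfig()
    if aln is None:
        aln = align_cds_pair(cds_a, cds_b, id_a, id_b)
    free = ml_pairwise_omega(aln, fix_omega=None, kappa=config.kappa,
                             codon_freq=config.codon_freq)
    null = ml_pairwise_omega(aln, fix_omega=config.omega_null,
                             kappa=config.kappa if config.kappa is not None else free.kappa_hat,
                             codon_freq=config.codon_freq)
    # guarantee nesting: the null can never beat the free model
    if null.lnL > free.lnL:
        refit = ml_pairwise_omega(aln, fix_omega=None, kappa=config.kappa,
                                  codon_freq=config.codon_freq)
        if refit.lnL > free.lnL:
            free = refit
        free = replace(free, lnL=max(free.lnL, null.lnL))
    if config.codon_freq == "f1x4":
        pi = f1x4_codon_frequencies([aln.seq_a.replace("-", ""), aln.seq_b.replace("-", "")])
    else:
        pi = uniform_codon_frequencies()
    ka, ks = ml_ka_ks(free, pi)
    p, neg = lrt_negative_selection(free.lnL, null.lnL, free.omega_hat,
                                    config.omega_null, config.alpha)
    return KaKsResult(id_a=id_a, id_b=id_b, ka=ka, ks=ks, omega=free.omega_hat,
                      lnL_free=free.lnL, lnL_null=null.lnL, p_value=p,
                      negative_selection=neg)


def filter_pairs(results: Sequence[KaKsResult],
                 config: SelectionConfig | None = None) -> list[KaKsResult]:
    """Annotate exclusion reasons: Ka > 0.5, Ks > 5, then the upper Tukey fence.

    The fence (Q3 + 1.5 IQR, quartiles by linear interpolation) is computed
    on the Ks values of pairs surviving the first two rules.  A pair called
    under negative selection loses the call when excluded.
    """
    config = config or SelectionConfig()
    out = []
    for r in results:
        reason = REASON_NONE
        if not math.isfinite(r.ka) or r.ka > config.ka_max:
            reason = REASON_KA
        elif not math.isfinite(r.ks) or r.ks > config.ks_max:
            reason = REASON_KS
        out.append(replace(r, excluded_reason=reason))
    survivors = [r for r in out if r.excluded_reason == REASON_NONE]
    if len(survivors) >= 2:
        ks = np.array([r.ks for r in survivors])
        q1, q3 = np.percentile(ks, [25, 75])
        fence = q3 + config.iqr_multiplier * (q3 - q1)
        for k, r in enumerate(out):
            if r.excluded_reason == REASON_NONE and r.ks > fence:
                out[k] = replace(r, excluded_reason=REASON_IQR)
    for k, r in enumerate(out):
        if r.excluded_reason != REASON_NONE and r.negative_selection:
            out[k] = replace(r, negative_selection=False)
    return out


def summarize_selection(results: Sequence[KaKsResult],
                        decimals: int = 2) -> tuple[int, int, float]:
    """(n_negative, n_tested, percent) over non-excluded pairs (half-up rounding)."""
    tested = [r for r in results if r.excluded_reason == REASON_NONE]
    if not tested:
        raise ValidationError("no tested pairs after filtering")
    n_neg = sum(1 for r in tested if r.negative_selection)
    return n_neg, len(tested), round_half_up(100.0 * n_neg / len(tested), decimals)


def results_to_frame(results: Sequence[KaKsResult]):
    import pandas as pd

    return pd.DataFrame([{
        "pair": f"{r.id_a}:{r.id_b}", "ka": r.ka, "ks": r.ks, "omega": r.omega,
        "lnL_free": r.lnL_free, "lnL_null": r.lnL_null, "p_value": r.p_value,
        "excluded_reason": r.excluded_reason,
        "negative_selection": r.negative_selection,
    } for r in results]).set_index("pair")
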