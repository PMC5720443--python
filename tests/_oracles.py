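"""Independent arbitrary-precision oracles for the BED formulas.

Direct evaluation of the survival-averaged BED expressions with the stdlib
``decimal`` module at 60 significant digits — no shifting tricks, no shared
code with the implementation under test.  ``Decimal(float)`` conversion is
exact, so the oracles consume the very same binary inputs the package sees.
"""

from decimal import Decimal, localcontext

import numpy as np

PREC = 60


def dec_neg_log_weighted_survival(weights, log_survivals) -> Decimal:
    """-ln sum_i v_i exp(ls_i) by direct 60-digit summation."""
    with localcontext() as ctx:
        ctx.prec = PREC
        total = Decimal(0)
        for w, ls in zip(weights, log_survivals):
            total += Decimal(float(w)) * Decimal(float(ls)).exp()
        return -total.ln()


def _dec_repop(alpha, teff, elapsed, includes_repop) -> Decimal:
    if not includes_repop:
        return Decimal(0)
    with localcontext() as ctx:
        ctx.prec = PREC
        return (
            Decimal(2).ln()
            * Decimal(float(elapsed))
            / (Decimal(float(alpha)) * Decimal(float(teff)))
        )


def dec_bed_conventional(n, d, alpha_beta, alpha=0.3, teff=13.0,
                         elapsed=0.0, includes_repop=False) -> Decimal:
    with localcontext() as ctx:
        ctx.prec = PREC
        dd = Decimal(float(d))
        val = Decimal(n) * dd * (1 + dd / Decimal(float(alpha_beta)))
        return val - _dec_repop(alpha, teff, elapsed, includes_repop)


def _dec_log_survivals(midpoints, n, alpha, alpha_beta):
    with localcontext() as ctx:
        ctx.prec = PREC
        a = Decimal(float(alpha))
        ab = Decimal(float(alpha_beta))
        out = []
        for m in midpoints:
            dm = Decimal(float(m))
            out.append(-a * Decimal(n) * dm * (1 + dm / ab))
        return out


def dec_bed_heterogeneous_cc(weights, midpoints, n, alpha, alpha_beta,
                             teff=13.0, elapsed=0.0,
                             includes_repop=False) -> Decimal:
    """Survival-averaged constant-case BED, evaluated directly."""
    with localcontext() as ctx:
        ctx.prec = PREC
        ls = _dec_log_survivals(midpoints, n, alpha, alpha_beta)
        total = Decimal(0)
        for w, l in zip(weights, ls):
            total += Decimal(float(w)) * l.exp()
        val = -total.ln() / Decimal(float(alpha))
        return val - _dec_repop(alpha, teff, elapsed, includes_repop)


def dec_bed_fraction_ivc(weights, midpoints, n, alpha, alpha_beta,
                         teff=13.0, elapsed=0.0,
                         includes_repop=False) -> Decimal:
    """Per-fraction survival-averaged BED with a 1/n repopulation share."""
    with localcontext() as ctx:
        ctx.prec = PREC
        ls = _dec_log_survivals(midpoints, 1, alpha, alpha_beta)
        total = Decimal(0)
        for w, l in zip(weights, ls):
            total += Decimal(float(w)) * l.exp()
        val = -total.ln() / Decimal(float(alpha))
        repop = _dec_repop(alpha, teff, elapsed, includes_repop) / Decimal(n)
        return val - repop


def dec_bed_total_ivc(weight_lists, midpoint_lists, alpha, alpha_beta,
                      teff=13.0, elapsed=0.0, includes_repop=False) -> Decimal:
    n = len(weight_lists)
    total = Decimal(0)
    for w, m in zip(weight_lists, midpoint_lists):
        total += dec_bed_fraction_ivc(
            w, m, n, alpha, alpha_beta, teff, elapsed, includes_repop
        )
    return total


def rel_err(value: float, oracle: Decimal) -> float:
    """|value - oracle| / |oracle| with 60-digit subtraction."""
    with localcontext() as ctx:
        ctx.prec = PREC
        o = Decimal(oracle)
        return float(abs(Decimal(float(value)) - o) / abs(o))


def two_pass_mean_sd(values) -> tuple[float, float]:
    """Independent two-pass mean / sample SD (n-1) without numpy reductions."""
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var**0.5


def shell_mean_numeric(prescription_dose, balloon_radius) -> float:
    """Mean dose over the 1 cm shell for a central point source, by an
    independent numerical integrator (volume-weighted radial quadrature)."""
    from scipy.integrate import quad

    r0 = balloon_radius + 1.0
    num, _ = quad(lambda r: prescription_dose * (r0 / r) ** 2 * r**2,
                  balloon_radius, r0)
    den, _ = quad(lambda r: r**2, balloon_radius, r0)
    return num / den
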