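"""Enzyme rate-law primitives.

All concentrations are mM, time is hours, rates are mM/h throughout the
package.  The laws here are the small closed-form building blocks the whole
model is assembled from:

* irreversible Michaelis-Menten for single-substrate steps,
* irreversible ordered bi-bi for the two condensations where neither
  substrate can be treated as in excess (the polyketide synthase/cyclase
  step and the aromatic prenyltransferase),
* (reversible) mass action for the isoprenoid couplings and the IPP/DMAPP
  isomerization,
* passive diffusion for hexanoic-acid uptake across the membrane,
* a zero-order feed term,
* a multiplicative Hill factor for glucose activation/repression of the
  two alcohol dehydrogenases.

Rate laws are pure functions: identical inputs give bit-identical outputs.
Scalar preconditions are enforced with :class:`InvalidArgumentError`; the ODE
right-hand side bypasses the checks (it clips solver excursions itself).
"""

from __future__ import annotations

import math

from .errors import InvalidArgumentError

__all__ = [
    "mm_rate",
    "bibi_rate",
    "mass_action_rate",
    "diffusion_rate",
    "zero_order_rate",
    "hill_factor",
]


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise InvalidArgumentError(f"{name} must be >= 0, got {value!r}")


def mm_rate(vmax: float, km: float, s: float) -> float:
    """Irreversible Michaelis-Menten rate ``vmax*s/(km+s)``.

    Parameters
    ----------
    vmax : float
        Limiting rate, mM/h.
    km : float
        Half-saturation constant, mM; must be positive.
    s : float
        Substrate concentration, mM.

    Returns
    -------
    float
        Rate in mM/h; zero at ``s=0``, monotone in ``s`` and bounded by ``vmax``.
    """
    _require_nonnegative(vmax=vmax, s=s)
    if km <= 0:
        raise InvalidArgumentError(f"km must be > 0, got {km!r}")
    return vmax * s / (km + s)


def bibi_rate(vmax: float, km_a: float, km_b: float, ki_a: float,
              a: float, b: float) -> float:
    """Irreversible ordered bi-bi rate (product terms omitted).

    ``v = vmax*a*b / (ki_a*km_b + km_b*a + km_a*b + a*b)``

    ``a`` binds first; ``ki_a`` is its dissociation constant from the free
    enzyme.  In the limit ``a >> km_a, ki_a`` the law collapses to
    Michaelis-Menten in ``b``.
    """
    _require_nonnegative(vmax=vmax, a=a, b=b)
    for name, value in (("km_a", km_a), ("km_b", km_b), ("ki_a", ki_a)):
        if value <= 0:
            raise InvalidArgumentError(f"{name} must be > 0, got {value!r}")
    return vmax * a * b / (ki_a * km_b + km_b * a + km_a * b + a * b)


def mass_action_rate(k: float, substrates: tuple[float, ...],
                     k_rev: float = 0.0,
                     products: tuple[float, ...] = ()) -> float:
    """(Reversible) mass-action rate ``k*prod(substrates) - k_rev*prod(products)``.

    Used for the ERG20 prenyl couplings (irreversible, ``k_rev=0``) and the
    IDI1 isomerization (reversible).  For bimolecular steps ``k`` carries
    units mM^-1 h^-1.
    """
    _require_nonnegative(k=k, k_rev=k_rev)
    forward = k * math.prod(substrates)
    backward = k_rev * math.prod(products) if k_rev else 0.0
    return forward - backward


def diffusion_rate(k: float, s_out: float, s_in: float) -> float:
    """Passive diffusion flux ``k*(s_out - s_in)`` in mM/h of cytosol.

    Sign follows the gradient: positive for uptake, negative for efflux.
    """
    _require_nonnegative(k=k)
    return k * (s_out - s_in)


def zero_order_rate(k: float) -> float:
    """Constant feed term, mM/h."""
    _require_nonnegative(k=k)
    return k


def hill_factor(modifier: float, k_half: float, n: float, mode: str) -> float:
    """Multiplicative Hill regulation factor in [0, 1].

    ``mode='activate'`` gives ``m^n/(k^n+m^n)`` (rises with the modifier);
    ``mode='repress'`` gives ``k^n/(k^n+m^n)``.  Used for the glucose
    switching of ADH1 (active on glucose, Crabtree overflow to ethanol) and
    ADH2 (derepressed after glucose depletion, ethanol reconsumption).
    """
    _require_nonnegative(modifier=modifier)
    if k_half <= 0:
        raise InvalidArgumentError(f"k_half must be > 0, got {k_half!r}")
    if n < 1:
        raise InvalidArgumentError(f"hill n must be >= 1, got {n!r}")
    mn = modifier ** n
    kn = k_half ** n
    if mode == "activate":
        return mn / (kn + mn)
    if mode == "repress":
        return kn / (kn + mn)
    raise InvalidArgumentError(f"unknown regulation mode {mode!r}")
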