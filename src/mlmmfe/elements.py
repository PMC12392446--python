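"""Periodic-table element properties used by the element-embracing descriptors.

Each supported element (periods 1-5, s/p/d blocks, i.e. H through Xe) carries
seven descriptor channels: the constant 1, the period number ``n``, the
main-group number ``m`` (1-8 across the s- and p-blocks, fixed to 2 for the
d-block), the d-block column ``d`` (Sc=1 ... Zn=10; 0 for main-group
elements), and their reverse-order counterparts ``n_bar = X - n`` (with
X = 6, so the maximum period is 5), ``m_bar = 9 - m`` (7 for the d-block)
and ``d_bar = 11 - d`` (0 for main-group elements).

Reverse counting balances the representation of light and heavy elements:
an element rare on the forward scale is prominent on the reversed one.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ElementProperties",
    "element_properties",
    "is_supported",
    "SUPPORTED_ELEMENTS",
    "ATOMIC_NUMBERS",
    "ATOMIC_MASSES",
    "UnsupportedElementError",
]

_PERIOD_RANGES = {
    1: (1, 2),
    2: (3, 10),
    3: (11, 18),
    4: (19, 36),
    5: (37, 54),
}

_SYMBOLS = (
    "H He "
    "Li Be B C N O F Ne "
    "Na Mg Al Si P S Cl Ar "
    "K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe"
).split()

ATOMIC_NUMBERS: dict[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
SUPPORTED_ELEMENTS = frozenset(_SYMBOLS)

# Standard atomic weights (amu), rounded; used for MD masses only.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.94, "Be": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.95, "Tc": 98.0, "Ru": 101.07, "Rh": 102.906,
    "Pd": 106.42, "Ag": 107.868, "Cd": 112.414, "In": 114.818,
    "Sn": 118.710, "Sb": 121.760, "Te": 127.60, "I": 126.904, "Xe": 131.293,
}

#: Reverse-period offset X: n_bar = X - n, so the heaviest supported period is X - 1.
X_PERIOD_OFFSET = 6


class UnsupportedElementError(ValueError):
    """Raised for elements outside periods 1-5 of the s/p/d blocks."""


@dataclass(frozen=True)
class ElementProperties:
    """The seven element channels of one chemical element."""

    symbol: str
    n: int        # period number, 1..5
    m: int        # main-group number 1..8 (2 for d-block)
    d: int        # d-block column 1..10 (0 for main group)
    n_bar: int    # X - n
    m_bar: int    # 9 - m (7 for d-block)
    d_bar: int    # 11 - d (0 for main group)

    @property
    def channels(self) -> tuple[float, ...]:
        """Channel values in the canonical order (1, n, m, d, n_bar, m_bar, d_bar)."""
        return (1.0, float(self.n), float(self.m), float(self.d),
                float(self.n_bar), float(self.m_bar), float(self.d_bar))


#: Maximal channel values over the supported set, canonical channel order.
CHANNEL_NAMES = ("one", "n", "m", "d", "n_bar", "m_bar", "d_bar")
CHANNEL_MAX = (1.0, 5.0, 8.0, 10.0, 5.0, 8.0, 10.0)


def is_supported(symbol: str) -> bool:
    return symbol in SUPPORTED_ELEMENTS


def element_properties(symbol: str) -> ElementProperties:
    """Look up the descriptor channels of an element.

    Raises
    ------
    UnsupportedElementError
        If the element lies beyond period 5 or in the f-block.
    """
    z = ATOMIC_NUMBERS.get(symbol)
    if z is None:
        raise UnsupportedElementError(
            f"element {symbol!r} is not supported (periods 1-5, s/p/d blocks only)"
        )
    for period, (lo, hi) in _PERIOD_RANGES.items():
        if lo <= z <= hi:
            break
    pos = z - lo + 1  # position within the period
    width = hi - lo + 1
    if width == 2:  # period 1: H is group 1, He closes the shell (group 8)
        m, d = (1, 0) if pos == 1 else (8, 0)
    elif width == 8:  # periods 2-3: pure main group
        m, d = pos, 0
    else:  # periods 4-5: s-block (1-2), d-block (3-12), p-block (13-18)
        if pos <= 2:
            m, d = pos, 0
        elif pos <= 12:
            m, d = 2, pos - 2
        else:
            m, d = pos - 10, 0
    n_bar = X_PERIOD_OFFSET - period
    m_bar = 9 - m
    d_bar = (11 - d) if d > 0 else 0
    return ElementProperties(symbol, period, m, d, n_bar, m_bar, d_bar)
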