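"""Packaged nearest-neighbor RNA duplex parameters (Turner 2004 set).

Stack free energies (dG at 37 degC) and enthalpies (dH) for Watson-Crick and
G:U wobble dinucleotide steps, duplex initiation, and the terminal A:U / G:U
penalty, at the 0.1 kcal/mol precision of the published tables.  Pair order
and orientation follow the standard convention: ``STACK_DG37[p][q]`` is the
stack of closing pair ``p = (5' base + 3' partner)`` over the following pair
``q`` read from the opposite strand, so the stack of

    5'-X Y-3'
    3'-X'Y'-5'

is ``STACK_DG37[X + X'][Y' + Y]``.  Bases are RNA (A, C, G, U).

Version: turner-2004, dG/dH pairs enable linear dG(T) = dH - T * dS rescaling.
"""

from __future__ import annotations

PARAMETER_VERSION = "turner-2004"

_PAIRS = ("CG", "GC", "GU", "UG", "AU", "UA")

_DG_ROWS = {
    "CG": (-2.40, -3.30, -2.10, -1.40, -2.10, -2.10),
    "GC": (-3.30, -3.40, -2.50, -1.50, -2.20, -2.40),
    "GU": (-2.10, -2.50, +1.30, -0.50, -1.40, -1.30),
    "UG": (-1.40, -1.50, -0.50, +0.30, -0.60, -1.00),
    "AU": (-2.10, -2.20, -1.40, -0.60, -1.10, -0.90),
    "UA": (-2.10, -2.40, -1.30, -1.00, -0.90, -1.30),
}

_DH_ROWS = {
    "CG": (-10.60, -13.40, -12.10, -5.60, -10.50, -10.40),
    "GC": (-13.40, -14.90, -12.60, -8.30, -11.40, -12.40),
    "GU": (-12.10, -12.60, -14.60, -13.50, -8.80, -12.80),
    "UG": (-5.60, -8.30, -13.50, -9.30, -3.20, -7.00),
    "AU": (-10.50, -11.40, -8.80, -3.20, -9.40, -6.80),
    "UA": (-10.40, -12.40, -12.80, -7.00, -6.80, -7.70),
}

STACK_DG37: dict[str, dict[str, float]] = {
    p: dict(zip(_PAIRS, row)) for p, row in _DG_ROWS.items()
}
STACK_DH: dict[str, dict[str, float]] = {
    p: dict(zip(_PAIRS, row)) for p, row in _DH_ROWS.items()
}

#: duplex initiation, kcal/mol
INIT_DG37 = 4.10
INIT_DH = 3.60

#: penalty per terminal A:U or G:U closing pair, kcal/mol
TERMINAL_AU_DG37 = 0.50
TERMINAL_AU_DH = 3.70

#: simplified internal-loop charge for a run of k opposed mismatches
#: (no gaps are modelled): MM_OPEN + MM_EXTEND * (k - 1), kcal/mol
MM_OPEN = 1.70
MM_EXTEND = 1.10

T_REF = 310.15  # K (37 degC), reference temperature of the dG values


def stack_dg(pair5: str, pair3_rev: str, temperature_c: float = 37.0) -> float:
    """Stack dG for closing pair ``pair5`` over ``pair3_rev`` (see module
    docstring for orientation), linearly rescaled to ``temperature_c``."""
    try:
        dg37 = STACK_DG37[pair5][pair3_rev]
    except KeyError as exc:
        raise ValueError(f"no stack parameter for {pair5}/{pair3_rev}") from exc
    if abs(temperature_c - 37.0) < 1e-9:
        return dg37
    dh = STACK_DH[pair5][pair3_rev]
    return _rescale(dg37, dh, temperature_c)


def _rescale(dg37: float, dh: float, temperature_c: float) -> float:
    t_kelvin = temperature_c + 273.15
    ds = (dh - dg37) / T_REF
    return dh - t_kelvin * ds


def init_dg(temperature_c: float = 37.0) -> float:
    if abs(temperature_c - 37.0) < 1e-9:
        return INIT_DG37
    return _rescale(INIT_DG37, INIT_DH, temperature_c)


def terminal_au_dg(temperature_c: float = 37.0) -> float:
    if abs(temperature_c - 37.0) < 1e-9:
        return TERMINAL_AU_DG37
    return _rescale(TERMINAL_AU_DG37, TERMINAL_AU_DH, temperature_c)
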