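"""Shared independent oracles for the test suite."""

import sympy


def _z(p):
    """Standard-normal quantile via sympy's arbitrary-precision erfinv."""
    return float(sympy.sqrt(2) * sympy.erfinv(sympy.Float(2 * p - 1, 40)))


def oracle_dprime_criterion(hit, fa, offset):
    """High-precision d'/criterion, clamping adjusted rates like the
    implementation but going through a quantile routine independent of
    scipy's ppf."""
    h = min(max(hit - offset, offset), 1 - offset)
    f = min(max(fa + offset, offset), 1 - offset)
    return _z(h) - _z(f), -(_z(h) + _z(f)) / 2
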