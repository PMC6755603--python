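"""Exact money arithmetic.

All cost computations run on integer euro cents (or exact rational
multiples of a cent, when a sample total is divided by a cohort size).
Floating point enters only at presentation time, never in aggregation, so
per-case, sample and population tables agree to the cent by construction.
"""
from __future__ import annotations

from decimal import Decimal
from fractions import Fraction
from typing import Union

Amount = Union[int, float, str, Decimal, Fraction]


def to_cents(amount: Amount) -> int:
    """Convert a euro amount to integer cents, rounding half up.

    Floats are interpreted via their shortest decimal representation
    (``str``), so ``to_cents(13.37) == 1337`` exactly.
    """
    if isinstance(amount, bool):
        raise TypeError("boolean is not a money amount")
    if isinstance(amount, int):
        return amount * 100
    if isinstance(amount, Fraction):
        return int(round_half_up(amount * 100, digits=0))
    if isinstance(amount, float):
        amount = Decimal(str(amount))
    elif isinstance(amount, str):
        amount = Decimal(amount)
    scaled = Fraction(amount) * 100
    return int(round_half_up(scaled, digits=0))


def round_half_up(value: Fraction, digits: int = 2) -> Decimal:
    """Round a non-negative exact rational half-up to ``digits`` decimals."""
    if value < 0:
        return -round_half_up(-value, digits)
    scaled = value * Fraction(10) ** digits
    q, r = divmod(scaled.numerator, scaled.denominator)
    if 2 * r >= scaled.denominator:
        q += 1
    return Decimal(q).scaleb(-digits)


def cents_to_eur(cents: Union[int, Fraction]) -> Decimal:
    """Integer (or exact rational) cents -> Decimal euros with 2 decimals."""
    return round_half_up(Fraction(cents) / 100)


def fmt_eur(value: Union[Decimal, int, float, Fraction], locale: str = "en",
            symbol: bool = True) -> str:
    """Format a euro amount with thousands separators.

    ``locale='de'`` renders German style (dot thousands, comma decimals):
    ``260.704.250,62 €``; the default renders ``260,704,250.62``.
    """
    if isinstance(value, Fraction):
        value = round_half_up(value)
    d = Decimal(str(value)).quantize(Decimal("0.01"))
    text = f"{d:,.2f}"
    if locale == "de":
        text = text.translate(str.maketrans({",": ".", ".": ","}))
    elif locale != "en":
        raise ValueError(f"unknown locale: {locale!r}")
    return f"{text} €" if symbol else text


def parse_eur(text: str, locale: str = "en") -> Decimal:
    """Inverse of :func:`fmt_eur` (used for report round-trips)."""
    cleaned = text.replace("€", "").strip()
    if locale == "de":
        cleaned = cleaned.replace(".", "").replace(",", ".")
    else:
        cleaned = cleaned.replace(",", "")
    return Decimal(cleaned)
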