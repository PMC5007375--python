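"""Small shared helpers."""

from __future__ import annotations


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage of ``numerator/denominator`` rounded to ``digits`` decimals.

    This is the single formatting rule used everywhere a proportion is
    reported, so printed percentages are exactly reproducible from their
    count pairs.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return round(100.0 * numerator / denominator, digits)
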