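"""Normalization of National Drug Codes (NDC) to the 11-digit 5-4-2 form.

NDCs are printed in four 10-digit dashed segment patterns (4-4-2, 5-3-2,
5-4-1) plus the full 5-4-2; billing systems use an 11-digit undashed form in
which the deficient segment of a 10-digit code is left-padded with one zero
(the HIPAA convention).  All NDC equality tests in this package are performed
on the normalized 11-digit form.

An *undashed* 10-digit code is rejected rather than guessed: without the
dashes the deficient segment cannot be located, and a wrong guess silently
corrupts every downstream match.
"""

from __future__ import annotations

import re

from .errors import FormatError, NDCAmbiguityError

__all__ = ["normalize_ndc", "is_normalized_ndc"]

# segment lengths of the accepted dashed renderings, keyed by total digits
_DASHED = re.compile(r"^(\d{4,5})-(\d{3,4})-(\d{1,2})$")
_SEGMENT_TARGET = (5, 4, 2)


def is_normalized_ndc(value: str) -> bool:
    """True iff *value* is an 11-digit normalized NDC."""
    return len(value) == 11 and value.isdigit()


def normalize_ndc(raw: str) -> str:
    """Normalize a raw NDC string to the 11-digit 5-4-2 form.

    Parameters
    ----------
    raw:
        A dashed NDC in 4-4-2, 5-3-2, 5-4-1 or 5-4-2 segment form, or an
        undashed 11-digit code.  Surrounding whitespace is ignored.

    Returns
    -------
    str
        The 11-digit normalized code.

    Raises
    ------
    NDCAmbiguityError
        For undashed 10-digit input (deficient segment unlocatable).
    FormatError
        For any other shape.
    """
    code = raw.strip()
    if "-" not in code:
        if len(code) == 11 and code.isdigit():
            return code
        if len(code) == 10 and code.isdigit():
            raise NDCAmbiguityError(
                f"undashed 10-digit NDC {code!r} is ambiguous: cannot locate "
                "the segment to zero-pad"
            )
        raise FormatError(f"not a recognizable NDC: {raw!r}")

    m = _DASHED.match(code)
    if m is None:
        raise FormatError(f"not a recognizable dashed NDC: {raw!r}")
    segments = m.groups()
    deficits = [t - len(s) for s, t in zip(segments, _SEGMENT_TARGET)]
    if sum(deficits) not in (0, 1) or any(d < 0 for d in deficits):
        raise FormatError(f"not a recognizable dashed NDC: {raw!r}")
    return "".join(s.zfill(t) for s, t in zip(segments, _SEGMENT_TARGET))
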