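"""Canonical measure names and domain labels.

The analysis relates two domains measured on the same subjects:

* six neurocognitive sub-test scores (BACS battery) — verbal memory (VM),
  digit sequencing (DS), token motor task (TMT), verbal fluency (VF),
  symbol coding (SC) and Tower of London (TL); higher is better;
* six oculomotor summary measures — per-subject median anti-saccade
  latency (ASLs), median anti-saccade error latency (ASELs), anti-saccade
  error proportion (ASEs), median Go-saccade latency (GnGLs), median
  NoGo error-saccade latency (GnGELs) and NoGo error proportion (GnGEs);
  higher is worse.
"""

from __future__ import annotations

COGNITIVE_MEASURES: tuple[str, ...] = ("VM", "DS", "TMT", "VF", "SC", "TL")
OCULOMOTOR_MEASURES: tuple[str, ...] = (
    "ASLs",
    "ASELs",
    "ASEs",
    "GnGLs",
    "GnGELs",
    "GnGEs",
)
ALL_MEASURES: tuple[str, ...] = COGNITIVE_MEASURES + OCULOMOTOR_MEASURES

#: measure name -> domain ("cognitive" | "oculomotor")
DOMAINS: dict[str, str] = {
    **{m: "cognitive" for m in COGNITIVE_MEASURES},
    **{m: "oculomotor" for m in OCULOMOTOR_MEASURES},
}

#: significance codes carried by the printed correlation tables, ordered
#: from strongest to weakest; "ns" marks an uncoded (non-significant) cell.
SIG_CODES: tuple[str, ...] = (".001", ".01", ".05", ".1", "ns")

#: nominal p-value ceiling implied by each code ("ns" has no ceiling).
SIG_CODE_LEVELS: dict[str, float] = {".001": 0.001, ".01": 0.01, ".05": 0.05, ".1": 0.1}


def sig_code_for_p(p: float) -> str:
    """Map a p-value to the significance code a printed table would carry."""
    for code, level in SIG_CODE_LEVELS.items():
        if p < level:
            return code
    return "ns"
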