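"""TNM stage labels, regression grades, and response endpoints.

Stage labels follow AJCC/UICC 8th-edition text codes ("T3b", "N1c", ...).
For all score arithmetic the substage letter is discarded: the neoadjuvant
rectal (NAR) score is defined on integer stages, which is also the only
form the trial reports in its formulas. Response endpoints:

* pCR   -- pathologic complete response: pTRG 0 (no residual tumor cells)
           together with ypN0.
* near-pCR -- pTRG <= 1 (<10% residual tumor cells).
* radiologic complete response -- mrTRG 1 on post-treatment MRI.

Missing inputs propagate as ``None`` rather than defaulting, so each
downstream analysis can apply its own complete-case denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "StageValidationError",
    "PatientRecord",
    "encode_t_stage",
    "encode_n_stage",
    "validate_mrtrg",
    "validate_ptrg",
    "derive_pcr",
    "derive_near_pcr",
    "is_radiologic_complete",
]


class StageValidationError(ValueError):
    """Raised for a malformed stage label or out-of-range grade."""


# T0-T4 with an optional single substage letter; "Tis" maps to 0 (no
# in-situ tumors occur in a cT>=2 population, but the label is legal AJCC).
_T_RE = re.compile(r"^T(?:is|(?P<num>[0-4])(?P<sub>[a-d])?)$")
_N_RE = re.compile(r"^N(?P<num>[0-2])(?P<sub>[a-c])?$")


def encode_t_stage(label: str) -> int:
    """Encode a T-stage label to its integer stage (substage discarded).

    >>> encode_t_stage("T3b")
    3
    """
    if not isinstance(label, str):
        raise StageValidationError(f"T stage must be a string, got {label!r}")
    m = _T_RE.match(label.strip())
    if m is None:
        raise StageValidationError(f"invalid T stage label: {label!r}")
    num = m.group("num")
    return 0 if num is None else int(num)  # Tis -> 0


def encode_n_stage(label: str) -> int:
    """Encode an N-stage label to its integer stage: N0->0, N1*->1, N2*->2."""
    if not isinstance(label, str):
        raise StageValidationError(f"N stage must be a string, got {label!r}")
    m = _N_RE.match(label.strip())
    if m is None:
        raise StageValidationError(f"invalid N stage label: {label!r}")
    return int(m.group("num"))


def validate_mrtrg(grade: int) -> int:
    """Validate an MRI tumor regression grade (1 = complete response ... 5)."""
    if grade not in (1, 2, 3, 4, 5):
        raise StageValidationError(f"mrTRG must be in 1..5, got {grade!r}")
    return int(grade)


def validate_ptrg(grade: int) -> int:
    """Validate a pathologic tumor regression grade (0 = no residual tumor ... 3)."""
    if grade not in (0, 1, 2, 3):
        raise StageValidationError(f"pTRG must be in 0..3, got {grade!r}")
    return int(grade)


def derive_pcr(ptrg: Optional[int], ypn: Optional[str]) -> Optional[bool]:
    """pCR endpoint: pTRG 0 and ypN0.  Missing input -> ``None``."""
    if ptrg is None or ypn is None:
        return None
    return validate_ptrg(ptrg) == 0 and encode_n_stage(ypn) == 0


def derive_near_pcr(ptrg: Optional[int]) -> Optional[bool]:
    """Near-pCR endpoint: pTRG <= 1.  Missing input -> ``None``."""
    if ptrg is None:
        return None
    return validate_ptrg(ptrg) <= 1


def is_radiologic_complete(mrtrg: Optional[int]) -> Optional[bool]:
    """Radiologic complete response: mrTRG == 1.  Missing input -> ``None``."""
    if mrtrg is None:
        return None
    return validate_mrtrg(mrtrg) == 1


@dataclass
class PatientRecord:
    """One enrolled subject: stages, grades, densities, survival follow-up.

    Stage fields hold text labels (validated lazily by the encoders);
    densities are cells/mm^2; times are months from initial diagnosis.
    Any analysis field may be missing (``None``).
    """

    patient_id: str
    ct: Optional[str] = None          # baseline clinical T (cT, pre-TNT MRI)
    cn: Optional[str] = None          # baseline clinical N
    ypt: Optional[str] = None         # pathologic T after neoadjuvant therapy
    ypn: Optional[str] = None         # pathologic N after neoadjuvant therapy
    rt_post: Optional[str] = None     # post-treatment radiologic (MRI) T
    rn_post: Optional[str] = None     # post-treatment radiologic (MRI) N
    mrtrg: Optional[int] = None       # MRI tumor regression grade 1-5
    ptrg: Optional[int] = None        # pathologic tumor regression grade 0-3
    cd3_ct: Optional[float] = None    # CD3+ density, tumor core
    cd3_im: Optional[float] = None    # CD3+ density, invasive margin
    cd8_ct: Optional[float] = None    # CD8+ density, tumor core
    cd8_im: Optional[float] = None    # CD8+ density, invasive margin
    grade: Optional[int] = None       # tumor differentiation grade 1-3
    dfs_months: Optional[float] = None
    dfs_event: Optional[int] = None
    os_months: Optional[float] = None
    os_event: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise StageValidationError("patient_id must be non-empty")
        for name in ("cd3_ct", "cd3_im", "cd8_ct", "cd8_im"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise StageValidationError(f"{name} must be >= 0, got {v}")
        for name in ("dfs_months", "os_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise StageValidationError(f"{name} must be >= 0, got {v}")
        if self.mrtrg is not None:
            validate_mrtrg(self.mrtrg)
        if self.ptrg is not None:
            validate_ptrg(self.ptrg)
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise StageValidationError(f"grade must be 1..3, got {self.grade!r}")
        for name in ("dfs_event", "os_event"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise StageValidationError(f"{name} must be 0/1, got {v!r}")

    def has_densities(self) -> bool:
        return None not in (self.cd3_ct, self.cd3_im, self.cd8_ct, self.cd8_im)
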