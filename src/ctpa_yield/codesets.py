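"""ICD-9-CM / ICD-10-CM code sets defining a pulmonary-embolism discharge
diagnosis.

The default set is the standard explicit PE definition used for
admission-linked phenotyping: five ICD-9-CM codes (415.0, 415.11, 415.12,
415.13, 415.19) and eight ICD-10-CM codes (I26.0, I26.01, I26.02, I26.09,
I26.9, I26.90, I26.92, I26.99). Matching is exact membership after
normalization — no hierarchical prefix expansion, since the list already
enumerates both the headers (I26.0, I26.9) and their children.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import yaml

from .errors import CTPAYieldError
from .model import ICDVersion

__all__ = ["PECodeSet", "normalize_code", "is_pe_code", "DEFAULT_PE_CODESET",
           "load_codeset"]


def normalize_code(raw: str) -> str:
    """Normalize an ICD code: strip whitespace, uppercase, remove dots.

    Deterministic and idempotent; raises ``ValueError`` on empty/blank input.
    """
    if raw is None or not raw.strip():
        raise ValueError("ICD code must be non-empty")
    return raw.strip().upper().replace(".", "")


@dataclass(frozen=True)
class PECodeSet:
    """A named pair of normalized ICD-9/ICD-10 code sets."""

    icd9_codes: frozenset
    icd10_codes: frozenset
    name: str = "custom"

    def __post_init__(self):
        if not self.icd9_codes or not self.icd10_codes:
            raise ValueError("code sets must be non-empty")
        object.__setattr__(
            self, "icd9_codes", frozenset(normalize_code(c) for c in self.icd9_codes)
        )
        object.__setattr__(
            self, "icd10_codes", frozenset(normalize_code(c) for c in self.icd10_codes)
        )

    def codes_for(self, version: ICDVersion) -> frozenset:
        if version is ICDVersion.ICD9:
            return self.icd9_codes
        if version is ICDVersion.ICD10:
            return self.icd10_codes
        raise CTPAYieldError(f"unknown ICD version: {version!r}")


#: Frozen default: the explicit PE discharge-diagnosis definition.
DEFAULT_PE_CODESET = PECodeSet(
    icd9_codes=frozenset({"415.0", "415.11", "415.12", "415.13", "415.19"}),
    icd10_codes=frozenset(
        {"I26.0", "I26.01", "I26.02", "I26.09", "I26.9", "I26.90", "I26.92",
         "I26.99"}
    ),
    name="pe_default",
)


def is_pe_code(code: str, version: ICDVersion, codeset: PECodeSet = DEFAULT_PE_CODESET) -> bool:
    """True iff ``normalize_code(code)`` is a member of the version's set.

    Membership is invariant to dotting, case, and surrounding whitespace.
    """
    return normalize_code(code) in codeset.codes_for(version)


def load_codeset(path: Union[str, Path], name: str = "custom") -> PECodeSet:
    """Load a code set override from a YAML file with a ``codesets:`` section
    holding ``icd9:`` and ``icd10:`` lists of strings."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    section = cfg.get("codesets", cfg)
    try:
        icd9 = section["icd9"]
        icd10 = section["icd10"]
    except (KeyError, TypeError) as exc:
        raise CTPAYieldError(
            f"{path}: expected 'codesets:' with 'icd9:' and 'icd10:' lists"
        ) from exc
    return PECodeSet(frozenset(icd9), frozenset(icd10), name=name)
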