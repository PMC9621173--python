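"""ICD-10 code normalization, pattern matching and per-condition rule bundles.

Three exemplar conditions whose diagnosis coding is mandatory in English
hospital data once established are audited:

* **autism** — childhood autism (F84.0), atypical autism (F84.1) and
  Asperger's syndrome (F84.5);
* **dmpc** — type II diabetes mellitus with peripheral circulatory
  complications (E11.5), audited against the broader diabetes chapter;
* **pdd** — Parkinson's disease dementia (F02.3), audited against the
  broader dementia code family.

Each condition carries three pattern sets: the *index* set that identifies
the first (index) spell, the wider *consistency* set a subsequent spell must
mention to count as consistently coded, and a *related-condition* set whose
absence is itself a model feature (Parkinson's disease G20 for PDD; the
learning-disability block F70–F83 for autism).

Codes are stored dot-stripped and uppercase; ``E11.5`` and ``E115`` are the
same code.  A chapter-style prefix pattern (written ``E11-`` in coding
guidance) matches every code that starts with its stem, including the bare
stem itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import yaml

__all__ = [
    "ICDCode",
    "CodePattern",
    "ConditionSpec",
    "InvalidCodeError",
    "normalize_code",
    "matches",
    "matches_any",
    "condition_specs",
    "CONDITIONS",
    "specs_to_yaml",
    "specs_from_yaml",
]

#: Canonical condition names, in reporting order.
CONDITIONS = ("autism", "dmpc", "pdd")

# A normalized code is just a string; the alias documents intent at call sites.
ICDCode = str


class InvalidCodeError(ValueError):
    """Raised for empty/whitespace-only diagnosis code input."""


def normalize_code(raw: str) -> ICDCode:
    """Normalize an ICD-10 code string: strip whitespace, uppercase, drop dots.

    Normalization is idempotent and maps the dotted and undotted dialects
    onto the same value (``"F84.0"`` and ``"F840"`` both give ``"F840"``).

    Raises
    ------
    InvalidCodeError
        If the input is empty or whitespace-only.
    """
    code = raw.upper().replace(".", "").strip()
    if not code:
        raise InvalidCodeError(f"empty ICD-10 code: {raw!r}")
    return code


@dataclass(frozen=True)
class CodePattern:
    """A matching rule over normalized ICD-10 codes.

    ``prefix`` mode implements the chapter dash convention (``E11-`` covers
    E11, E110, E115, ...); ``exact`` mode matches one code only.
    """

    stem: str
    mode: Literal["exact", "prefix"] = "exact"

    def __post_init__(self) -> None:
        stem = normalize_code(self.stem)  # raises on empty
        object.__setattr__(self, "stem", stem)
        if self.mode not in ("exact", "prefix"):
            raise ValueError(f"unknown pattern mode {self.mode!r}")

    def matches(self, code: ICDCode) -> bool:
        if self.mode == "prefix":
            return code.startswith(self.stem)
        return code == self.stem


def matches(pattern: CodePattern, code: ICDCode) -> bool:
    """True iff ``pattern`` covers the (already normalized) ``code``."""
    return pattern.matches(code)


def matches_any(patterns: Iterable[CodePattern], codes: Iterable[ICDCode]) -> bool:
    """True iff any pattern covers any of the codes."""
    codes = list(codes)
    return any(p.matches(c) for p in patterns for c in codes)


def _exacts(*stems: str) -> tuple[CodePattern, ...]:
    return tuple(CodePattern(s, "exact") for s in stems)


def _prefixes(*stems: str) -> tuple[CodePattern, ...]:
    return tuple(CodePattern(s, "prefix") for s in stems)


@dataclass(frozen=True)
class ConditionSpec:
    """The audit rule bundle for one condition."""

    name: str
    index_patterns: tuple[CodePattern, ...]
    consistency_patterns: tuple[CodePattern, ...]
    related_patterns: tuple[CodePattern, ...] = field(default_factory=tuple)
    min_age_years: int | None = None

    def __post_init__(self) -> None:
        # An index spell must be consistent with itself: every index stem
        # has to be covered by the consistency set.
        for p in self.index_patterns:
            if not any(c.matches(p.stem) for c in self.consistency_patterns):
                raise ValueError(
                    f"{self.name}: index pattern {p.stem} not covered by "
                    "consistency set"
                )

    def is_index(self, codes: Iterable[ICDCode]) -> bool:
        return matches_any(self.index_patterns, codes)

    def is_consistent(self, codes: Iterable[ICDCode]) -> bool:
        return matches_any(self.consistency_patterns, codes)

    def has_related(self, codes: Iterable[ICDCode]) -> bool:
        return matches_any(self.related_patterns, codes)


def condition_specs() -> dict[str, ConditionSpec]:
    """The three audited conditions with their published rule bundles.

    * autism: index = consistency = {F84.0, F84.1, F84.5}; related =
      learning-disability prefixes F70–F83.
    * dmpc: index = E11.5; consistency = diabetes prefixes E10-, E11-, E14-;
      no related set.
    * pdd: index = F02.3; consistency = dementia prefixes F00-, F01-, F02-,
      F03- plus F05.1, G30.1, G30.8, G30.9; related = Parkinson's disease G20.
    """
    return {
        "autism": ConditionSpec(
            name="autism",
            index_patterns=_exacts("F840", "F841", "F845"),
            consistency_patterns=_exacts("F840", "F841", "F845"),
            related_patterns=_prefixes(
                "F70", "F71", "F72", "F73", "F78", "F79",
                "F80", "F81", "F82", "F83",
            ),
            min_age_years=None,
        ),
        "dmpc": ConditionSpec(
            name="dmpc",
            index_patterns=_exacts("E115"),
            consistency_patterns=_prefixes("E10", "E11", "E14"),
            related_patterns=(),
            min_age_years=18,
        ),
        "pdd": ConditionSpec(
            name="pdd",
            index_patterns=_exacts("F023"),
            consistency_patterns=_prefixes("F00", "F01", "F02", "F03")
            + _exacts("F051", "G301", "G308", "G309"),
            related_patterns=_exacts("G20"),
            min_age_years=40,
        ),
    }


# ---------------------------------------------------------------------------
# Serialization: rule bundles as a YAML document so new conditions can be
# audited without code changes.

def _pattern_to_obj(p: CodePattern) -> dict:
    return {"stem": p.stem, "mode": p.mode}


def _spec_to_obj(spec: ConditionSpec) -> dict:
    return {
        "index": [_pattern_to_obj(p) for p in spec.index_patterns],
        "consistency": [_pattern_to_obj(p) for p in spec.consistency_patterns],
        "related": [_pattern_to_obj(p) for p in spec.related_patterns],
        "min_age_years": spec.min_age_years,
    }


def specs_to_yaml(specs: Mapping[str, ConditionSpec], path: str | Path) -> None:
    """Write condition rule bundles to a YAML rules file."""
    obj = {name: _spec_to_obj(s) for name, s in specs.items()}
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def specs_from_yaml(path: str | Path) -> dict[str, ConditionSpec]:
    """Read condition rule bundles from a YAML rules file."""
    obj = yaml.safe_load(Path(path).read_text())
    out: dict[str, ConditionSpec] = {}
    for name, body in obj.items():
        out[name] = ConditionSpec(
            name=name,
            index_patterns=tuple(
                CodePattern(p["stem"], p["mode"]) for p in body["index"]
            ),
            consistency_patterns=tuple(
                CodePattern(p["stem"], p["mode"]) for p in body["consistency"]
            ),
            related_patterns=tuple(
                CodePattern(p["stem"], p["mode"]) for p in body.get("related", [])
            ),
            min_age_years=body.get("min_age_years"),
        )
    return out
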