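"""Category maps: ICD-10 chapter ranges and ATC-style medication categories.

The analysis works with 16 comorbidity chapters and 60 medication
categories.  Real code lists vary by data vendor, so the maps ship as an
editable YAML document (``polyfrac/data/category_maps.yaml``) and are
loaded into a :class:`CategoryMaps` object that resolves raw codes.

ICD-10 codes are resolved by their letter + two leading digits against
half-open chapter ranges (e.g. ``K59.0`` falls in K00-K93, the digestive
chapter).  Drug codes are resolved by their 5-character prefix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import ConfigError, MappingError

N_CHAPTERS = 16
N_MED_CATEGORIES = 60

#: ICD-10 prefix of the case-defining diagnosis (femoral fracture).
CASE_CODE_PREFIX = "S72"

_CODE_RE = re.compile(r"^([A-Z])(\d\d)")


def _code_key(code: str) -> tuple[str, int] | None:
    m = _CODE_RE.match(code.strip().upper())
    if m is None:
        return None
    return m.group(1), int(m.group(2))


def _parse_range(rng: str) -> tuple[str, int, str, int]:
    lo, hi = rng.split("-")
    klo, khi = _code_key(lo), _code_key(hi)
    if klo is None or khi is None:
        raise ConfigError(f"icd10_chapters.ranges: malformed range {rng!r}")
    return (*klo, *khi)


@dataclass(frozen=True)
class CategoryMaps:
    """Resolver from raw claims codes to analysis categories."""

    chapter_keys: list[str]
    chapter_names: list[str]
    chapter_ranges: dict[str, list[tuple[str, int, str, int]]]
    med_prefixes: list[str]
    med_names: list[str]
    _prefix_to_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.chapter_keys) != N_CHAPTERS:
            raise ConfigError(
                f"icd10_chapters: expected {N_CHAPTERS} chapters, got {len(self.chapter_keys)}"
            )
        if len(self.med_prefixes) != N_MED_CATEGORIES:
            raise ConfigError(
                f"medication_categories: expected {N_MED_CATEGORIES}, got {len(self.med_prefixes)}"
            )
        if len(set(self.med_prefixes)) != len(self.med_prefixes):
            raise ConfigError("medication_categories.prefix: prefixes overlap")
        object.__setattr__(
            self, "_prefix_to_index", {p: i for i, p in enumerate(self.med_prefixes)}
        )

    # -- ICD-10 -----------------------------------------------------------
    def chapter_index(self, code: str) -> int | None:
        """0-based chapter index for an ICD-10 code, None if unmapped."""
        key = _code_key(code)
        if key is None:
            return None
        letter, num = key
        for i, ck in enumerate(self.chapter_keys):
            for llo, nlo, lhi, nhi in self.chapter_ranges[ck]:
                if (letter, num) >= (llo, nlo) and (letter, num) <= (lhi, nhi):
                    return i
        return None

    def chapter_of(self, code: str) -> str | None:
        i = self.chapter_index(code)
        return None if i is None else self.chapter_keys[i]

    # -- drugs ------------------------------------------------------------
    def med_index(self, drug_code: str) -> int | None:
        """0-based medication-category index from the 5-char code prefix."""
        return self._prefix_to_index.get(drug_code.strip()[:5])

    def med_indices(self, drug_codes) -> "list[int]":
        """Vector resolution; raises MappingError listing unmapped codes."""
        out, bad = [], set()
        for c in drug_codes:
            i = self.med_index(c)
            if i is None:
                bad.add(c)
            out.append(i)
        if bad:
            raise MappingError(f"unmapped drug codes: {sorted(bad)[:20]}")
        return out

    @property
    def chapter_variables(self) -> list[str]:
        return [f"cm_{k}" for k in self.chapter_keys]

    @property
    def med_variables(self) -> list[str]:
        return [f"rx{i + 1:02d}" for i in range(N_MED_CATEGORIES)]

    def variable_labels(self) -> dict[str, str]:
        """Map analysis variable names to their human-readable labels."""
        labels = {"med_count": "Number of medications"}
        labels.update(zip(self.chapter_variables, self.chapter_names))
        labels.update(zip(self.med_variables, self.med_names))
        return labels

    @classmethod
    def from_dict(cls, doc: dict) -> "CategoryMaps":
        try:
            chapters = doc["icd10_chapters"]
            meds = doc["medication_categories"]
        except KeyError as e:  # pragma: no cover - config plumbing
            raise ConfigError(f"category maps: missing section {e}") from e
        keys = [c["key"] for c in chapters]
        names = [c["name"] for c in chapters]
        ranges = {c["key"]: [_parse_range(r) for r in c["ranges"]] for c in chapters}
        return cls(
            chapter_keys=keys,
            chapter_names=names,
            chapter_ranges=ranges,
            med_prefixes=[m["prefix"] for m in meds],
            med_names=[m["name"] for m in meds],
        )

    @classmethod
    def from_yaml(cls, path=None) -> "CategoryMaps":
        """Load maps from a YAML file, or the packaged default when None."""
        if path is None:
            text = (
                resources.files("polyfrac").joinpath("data/category_maps.yaml").read_text()
            )
        else:
            with open(path, "r", encoding="utf-8") as fh:
                text = fh.read()
        return cls.from_dict(yaml.safe_load(text))


def default_maps() -> CategoryMaps:
    return CategoryMaps.from_yaml(None)
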