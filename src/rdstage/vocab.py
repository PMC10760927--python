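"""Code vocabularies for eligibility and metastasis detection.

Two small controlled vocabularies drive the staging rules:

* the ICD-O-3 morphology/behaviour and topography codes that define an
  eligible pancreatic carcinoma (a whitelist — neuroendocrine tumours are
  excluded simply by not being listed), and
* the ICD-10-AM secondary-malignancy block C77–C79 used to detect
  metastatic disease from hospital admitted-episode coding.

Both ship as plain-text, versioned data files under :mod:`rdstage.data`
so they can be audited and replaced without touching code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "HistologyCode",
    "TopographyCode",
    "ICD10AMCode",
    "Vocabulary",
    "VocabularyError",
    "load_default_vocabulary",
    "is_metastatic_site_code",
    "PANCREATIC_TOPOGRAPHY",
]

VOCAB_VERSION = "1.0"

#: The seven ICD-O-3 pancreatic topography codes.
PANCREATIC_TOPOGRAPHY = frozenset(
    {"C250", "C251", "C252", "C253", "C257", "C258", "C259"}
)

_MORPHOLOGY_RE = re.compile(r"^(\d{4})/(\d)$")
_TOPOGRAPHY_RE = re.compile(r"^C\d{3}$")
_ICD10_RE = re.compile(r"^([A-Z]\d{2})(?:\.?(\d{1,2}))?$")


class VocabularyError(ValueError):
    """A code string is malformed or a vocabulary file cannot be parsed."""


@dataclass(frozen=True)
class HistologyCode:
    """ICD-O-3 morphology + behaviour, canonical text form ``MMMM/B``."""

    morphology: str
    behaviour: str

    def __post_init__(self) -> None:
        if not re.fullmatch(r"\d{4}", self.morphology) or not (
            8000 <= int(self.morphology) <= 9999
        ):
            raise VocabularyError(
                f"histology morphology must be a 4-digit code in 8000-9999, "
                f"got {self.morphology!r}"
            )
        if self.behaviour not in {"0", "1", "2", "3", "6", "9"}:
            raise VocabularyError(
                f"histology behaviour must be one of 0,1,2,3,6,9, got "
                f"{self.behaviour!r}"
            )

    @classmethod
    def parse(cls, text: str) -> "HistologyCode":
        m = _MORPHOLOGY_RE.match(str(text).strip())
        if not m:
            raise VocabularyError(
                f"histology code must have form MMMM/B, got {text!r}"
            )
        return cls(morphology=m.group(1), behaviour=m.group(2))

    def __str__(self) -> str:
        return f"{self.morphology}/{self.behaviour}"


@dataclass(frozen=True)
class TopographyCode:
    """ICD-O-3 topography site code of form ``Cddd`` (e.g. C250)."""

    site: str

    def __post_init__(self) -> None:
        if not _TOPOGRAPHY_RE.match(self.site):
            raise VocabularyError(
                f"topography code must have form Cddd, got {self.site!r}"
            )

    @classmethod
    def parse(cls, text: str) -> "TopographyCode":
        return cls(site=str(text).strip().upper())

    @property
    def is_pancreatic(self) -> bool:
        return self.site in PANCREATIC_TOPOGRAPHY

    def __str__(self) -> str:
        return self.site


@dataclass(frozen=True)
class ICD10AMCode:
    """ICD-10-AM diagnosis code, optionally with a decimal subdivision."""

    code: str

    def __post_init__(self) -> None:
        if not _ICD10_RE.match(self.code):
            raise VocabularyError(
                f"ICD-10-AM code must look like C78 or C78.7, got {self.code!r}"
            )

    @classmethod
    def parse(cls, text: str) -> "ICD10AMCode":
        return cls(code=str(text).strip().upper())

    @property
    def category(self) -> str:
        """The 3-character category, subdivision stripped (C78.7 -> C78)."""
        return _ICD10_RE.match(self.code).group(1)

    def __str__(self) -> str:
        return self.code


def is_metastatic_site_code(code: ICD10AMCode | str) -> bool:
    """True iff the code's category lies in the secondary-malignancy
    block C77–C79, regardless of decimal subdivision.

    C77 (secondary lymph-node involvement) is included here; whether a
    staging run treats C77 as distant (M1) evidence is a policy switch on
    the engine, not on the vocabulary.
    """
    if isinstance(code, str):
        code = ICD10AMCode.parse(code)
    return code.category in {"C77", "C78", "C79"}


def _read_two_column(path: Path) -> dict[str, str]:
    table: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise VocabularyError(
                f"{path.name}:{lineno}: expected two tab-separated columns"
            )
        table[parts[0].strip()] = parts[1].strip()
    return table


@dataclass(frozen=True)
class Vocabulary:
    """Loaded eligibility vocabulary: histology whitelist + pancreatic sites."""

    histology: frozenset[str]
    topography: frozenset[str]
    version: str = VOCAB_VERSION

    def is_eligible(
        self, histology: HistologyCode | str, topography: TopographyCode | str
    ) -> bool:
        """True iff the morphology/behaviour pair is whitelisted and the
        topography is a pancreatic site.

        Eligibility is whitelist-based: any morphology absent from the
        shipped list — every neuroendocrine morphology among them — is
        ineligible, as are behaviours other than /3.
        """
        if isinstance(histology, str):
            histology = HistologyCode.parse(histology)
        if isinstance(topography, str):
            topography = TopographyCode.parse(topography)
        return str(histology) in self.histology and topography.site in self.topography


def load_vocabulary(
    histology_file: Path | str, topography_file: Path | str
) -> Vocabulary:
    """Load a vocabulary from two-column (code TAB description) text files."""
    return Vocabulary(
        histology=frozenset(_read_two_column(Path(histology_file))),
        topography=frozenset(_read_two_column(Path(topography_file))),
    )


def load_default_vocabulary(vocab_dir: Path | str | None = None) -> Vocabulary:
    """Load the packaged vocabulary, or one from ``vocab_dir`` if given."""
    if vocab_dir is not None:
        base = Path(vocab_dir)
    else:
        base = resources.files("rdstage") / "data"
    return load_vocabulary(
        Path(str(base / "histology_icdo3.tsv")),
        Path(str(base / "topography_icdo3.tsv")),
    )
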