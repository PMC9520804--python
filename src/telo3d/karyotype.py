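"""Simplified ISCN karyotype parsing for CML clonal-evolution counting.

Parses the subset of ISCN nomenclature needed to read clinical CML
karyotypes — clones separated by ``/``, a modal chromosome count (possibly a
range such as ``46-48``), a sex designation, abnormality tokens (``t``,
``del``, ``add``, ``der``, ``i``/``iso``, ``inv``, ``dup``, ``+N``/``-N``)
and cell counts in square brackets — and answers two questions: does a clone
carry the Philadelphia translocation t(9;22), and which abnormalities are
newly acquired between two disease phases of the same patient.

Typographic variants seen in clinical tables are normalised before
comparison: spaces are stripped, en-dashes become hyphens, and commas inside
parentheses (``t(9,22)``) become semicolons.  Ph detection matches
translocations by chromosome set {9, 22} regardless of breakpoints.
This is deliberately not a full ISCN grammar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib.resources import files

import pandas as pd


class KaryotypeParseError(ValueError):
    """Unparseable karyotype text, naming the offending token and position."""


_NUMERIC_RE = re.compile(r"^[+-](\d+|[XY])$")
_STRUCT_RE = re.compile(
    r"^([+-]?)(t|del|add|der|inv|dup|ins|i|iso)((?:\([0-9XYpqter.;\-]+\))+)$"
)
_SEX_RE = re.compile(r"^[XY]{1,4}$")
_COUNT_RE = re.compile(r"^(\d+)(?:-(\d+))?$")
_BRACKET_RE = re.compile(r"^(.*?)\[(\d+)\]$")


@dataclass(frozen=True)
class Abnormality:
    """One normalized abnormality token, optionally with its own cell count."""

    token: str
    n_cells: int | None = None

    def format(self) -> str:
        return self.token + (f"[{self.n_cells}]" if self.n_cells is not None else "")

    @property
    def is_translocation(self) -> bool:
        return re.match(r"^\+?t\(", self.token) is not None

    @property
    def translocation_chromosomes(self) -> frozenset[str]:
        """Chromosomes of the first parenthesis group of a t(...) token."""
        if not self.is_translocation:
            return frozenset()
        first = self.token[self.token.index("(") + 1 :].split(")")[0]
        return frozenset(first.split(";"))


@dataclass
class Clone:
    """One clonal line of a karyotype."""

    count_min: int
    count_max: int
    sex: str
    abnormalities: list[Abnormality] = field(default_factory=list)
    n_cells: int | None = None

    def format(self) -> str:
        count = (
            str(self.count_min)
            if self.count_min == self.count_max
            else f"{self.count_min}-{self.count_max}"
        )
        parts = [count, self.sex] + [a.format() for a in self.abnormalities]
        out = ",".join(p for p in parts if p)
        if self.n_cells is not None:
            out += f"[{self.n_cells}]"
        return out


@dataclass
class Karyotype:
    """A parsed karyotype: one or more clones plus the original string."""

    clones: list[Clone]
    raw: str

    def format(self) -> str:
        return "/".join(c.format() for c in self.clones)

    def abnormality_tokens(self) -> set[str]:
        return {a.token for c in self.clones for a in c.abnormalities}


def _normalize(text: str) -> str:
    text = text.replace("–", "-").replace("−", "-")
    text = re.sub(r"\s+", "", text)
    # commas are clone-level separators only at parenthesis depth 0;
    # inside parentheses they are typos for ';'
    out = []
    depth = 0
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        elif ch == "," and depth > 0:
            ch = ";"
        out.append(ch)
    return "".join(out)


def _parse_clone(text: str, offset: int) -> Clone:
    if not text:
        raise KaryotypeParseError(f"empty clone at position {offset}")
    n_cells = None
    m = _BRACKET_RE.match(text)
    if m:
        text, n_cells = m.group(1), int(m.group(2))
        if n_cells < 1:
            raise KaryotypeParseError(f"cell count must be >= 1 at position {offset}")
    tokens = [t for t in text.split(",") if t != ""]
    if not tokens:
        raise KaryotypeParseError(f"clone has no tokens at position {offset}")
    m = _COUNT_RE.match(tokens[0])
    if not m:
        raise KaryotypeParseError(
            f"expected chromosome count, got {tokens[0]!r} at position {offset}"
        )
    count_min = int(m.group(1))
    count_max = int(m.group(2)) if m.group(2) else count_min
    if count_max < count_min:
        raise KaryotypeParseError(f"invalid count range {tokens[0]!r} at position {offset}")
    tokens = tokens[1:]
    sex = ""
    if tokens and _SEX_RE.match(tokens[0]):
        sex = tokens[0]
        tokens = tokens[1:]
    abns = []
    for tok in tokens:
        cells = None
        m = _BRACKET_RE.match(tok)
        if m:
            tok, cells = m.group(1), int(m.group(2))
        if _NUMERIC_RE.match(tok) or _STRUCT_RE.match(tok):
            abns.append(Abnormality(tok, cells))
        else:
            raise KaryotypeParseError(
                f"unparseable abnormality token {tok!r} at position {offset}"
            )
    return Clone(count_min, count_max, sex, abns, n_cells)


def parse_karyotype(text: str) -> Karyotype:
    """Parse a (simplified) ISCN karyotype string into clones."""
    if not text or not text.strip():
        raise KaryotypeParseError("empty karyotype string")
    norm = _normalize(text)
    clones = []
    pos = 0
    for part in norm.split("/"):
        clones.append(_parse_clone(part, pos))
        pos += len(part) + 1
    return Karyotype(clones, raw=text)


def has_philadelphia(karyotype: Karyotype) -> bool:
    """True iff any clone carries a translocation involving both 9 and 22.

    Breakpoints are deliberately ignored: clinical tables write the Ph
    translocation with variant breakpoints (q11.2, q12) and variant
    separators, all of which denote the same t(9;22).
    """
    for clone in karyotype.clones:
        for abn in clone.abnormalities:
            if {"9", "22"} <= set(abn.translocation_chromosomes):
                return True
    return False


def _is_ph_token(token: str) -> bool:
    return {"9", "22"} <= set(Abnormality(token).translocation_chromosomes)


def additional_abnormalities(chronic: Karyotype, blast: Karyotype) -> set[str]:
    """Abnormality tokens present in the blast phase but absent in chronic.

    The Philadelphia translocation itself is excluded whenever both phases
    carry it (breakpoint typos would otherwise count it as new).
    """
    chronic_tokens = chronic.abnormality_tokens()
    extra = blast.abnormality_tokens() - chronic_tokens
    if has_philadelphia(chronic) and has_philadelphia(blast):
        extra = {t for t in extra if not _is_ph_token(t)}
    return extra


@dataclass(frozen=True)
class CytogeneticSummary:
    n_patients: int
    n_with_additional_abnormalities: int
    n_ph_negative_blast: int
    per_patient: pd.DataFrame


def cohort_cytogenetic_summary(pairs) -> CytogeneticSummary:
    """Summarise chronic-vs-blast clonal evolution over (chronic, blast) pairs.

    Counts patients acquiring at least one additional blast-phase abnormality
    and blast-phase karyotypes lacking the Ph chromosome.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no karyotype pairs provided")
    rows = []
    for i, (chronic, blast) in enumerate(pairs):
        extra = additional_abnormalities(chronic, blast)
        rows.append(
            {
                "patient": i + 1,
                "additional_abnormalities": ";".join(sorted(extra)),
                "n_additional": len(extra),
                "ph_chronic": has_philadelphia(chronic),
                "ph_blast": has_philadelphia(blast),
            }
        )
    per_patient = pd.DataFrame(rows)
    return CytogeneticSummary(
        n_patients=len(pairs),
        n_with_additional_abnormalities=int((per_patient["n_additional"] > 0).sum()),
        n_ph_negative_blast=int((~per_patient["ph_blast"]).sum()),
        per_patient=per_patient,
    )


def load_cytogenetics_table(path=None) -> pd.DataFrame:
    """Load a patient/chronic/blast karyotype table (default: packaged CML cohort)."""
    if path is None:
        with files("telo3d.data").joinpath("cml_cytogenetics.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"patient", "chronic_karyotype", "blast_karyotype"}
    if not required <= set(df.columns):
        raise ValueError(f"cytogenetics table must have columns {sorted(required)}")
    return df


def summarize_table(df: pd.DataFrame) -> CytogeneticSummary:
    pairs = [
        (parse_karyotype(row.chronic_karyotype), parse_karyotype(row.blast_karyotype))
        for row in df.itertuples()
    ]
    summary = cohort_cytogenetic_summary(pairs)
    summary.per_patient["patient"] = df["patient"].to_numpy()
    return summary
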