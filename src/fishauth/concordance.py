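"""Label-vs-genetics concordance and mislabelling rates.

Each retail sample carries a labelled species, an optional catch area
and a processing level (1 fresh/frozen fillet ... 5 fishcake).  A rule
table maps (label, area) to the set of genetic species groups that
would make the label truthful; generic "cod" with no stated area
accepts either Atlantic or Pacific cod, whereas cod explicitly sold as
Atlantic only accepts *Gadus morhua*.  Mixed-composition products
always count as mislabelled.

Rates are reported as raw fractions plus display percentages rounded
half-up to two decimals.  Denominators are the DNA-analysable samples;
samples whose DNA failed entirely (UNRESOLVED) are excluded.  The
survey's mislabelled products are shipped as a packaged fixture so its
summary table can be reproduced without the raw plate or trace data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from . import taxa
from .barcode import ReconciledID

__all__ = [
    "SampleRecord",
    "CongruenceRule",
    "RuleTable",
    "Verdict",
    "Stratum",
    "MislabellingSummary",
    "Table2Fixture",
    "default_rules",
    "congruence_verdict",
    "summarize",
    "summarize_fixture",
    "excess_landings",
    "binomial_ci",
    "load_table2_fixture",
    "display_pct",
]

PROCESSING_LEVELS = {
    1: "fresh or frozen fillets",
    2: "battered or breaded fillets",
    3: "fish fingers",
    4: "pre-cooked meals",
    5: "fishcakes",
}

# Reference volumes for the landings extrapolation (user inputs, in
# tonnes): total 2011 haddock landings against which a
# haddock-declared-but-cod rate is scaled, and the 2011 Atlantic cod
# quota the excess is expressed against.
HADDOCK_REFERENCE_LANDINGS_2011 = 56_537.0
ATLANTIC_COD_TAC_2011 = 75_448.0

_TABLE2_SHA256 = "f014ad7735033cf4a0780fd50497140b0535ff844fcdb8e3b9667d5e5c72359f"


@dataclass(frozen=True)
class SampleRecord:
    """One retail product."""

    sample_id: str
    label_species: str
    catch_area: str  # Atlantic | Pacific | NA
    processing_level: int
    plate_id: str | None = None
    well: str | None = None

    def __post_init__(self):
        if not self.label_species:
            raise ValueError(f"sample {self.sample_id}: empty label")
        if self.processing_level not in PROCESSING_LEVELS:
            raise ValueError(
                f"sample {self.sample_id}: processing level {self.processing_level} not in 1-5"
            )


@dataclass(frozen=True)
class CongruenceRule:
    label: str
    accept: frozenset[str]
    area: str | None = None  # None matches any catch area

    def matches(self, label: str, area: str) -> bool:
        if self.label != label:
            return False
        return self.area is None or self.area == area


class RuleTable:
    """Total mapping from (label, catch area) to acceptable groups."""

    def __init__(self, rules: Sequence[CongruenceRule]):
        self.rules = list(rules)

    def lookup(self, label: str, area: str) -> CongruenceRule:
        """Most specific matching rule (explicit area beats wildcard)."""
        matching = [r for r in self.rules if r.matches(label, area)]
        if not matching:
            raise KeyError(f"no congruence rule for label {label!r} (area {area!r})")
        matching.sort(key=lambda r: r.area is None)
        return matching[0]

    @classmethod
    def from_json(cls, path_or_dict) -> "RuleTable":
        if isinstance(path_or_dict, dict):
            data = path_or_dict
        else:
            with open(path_or_dict) as fh:
                data = json.load(fh)
        rules = [
            CongruenceRule(
                label=r["label"],
                area=r.get("area"),
                accept=frozenset(r["accept"]),
            )
            for r in data["rules"]
        ]
        return cls(rules)


def default_rules() -> RuleTable:
    """The packaged rule table for the survey's label vocabulary."""
    text = resources.files("fishauth.data").joinpath("congruence_rules.json").read_text()
    return RuleTable.from_json(json.loads(text))


@dataclass(frozen=True)
class Verdict:
    sample_id: str
    verdict: str  # CORRECT | MISLABELLED | UNRESOLVED
    reason: str | None  # substitution | mixed | ambiguous | None
    genetic: ReconciledID


def congruence_verdict(
    sample: SampleRecord, genetic: ReconciledID, rules: RuleTable
) -> Verdict:
    """Compare a sample's label against its reconciled genetic ID.

    MIXED reconciliations are always mislabelled.  An exact
    cross-group tie (AMBIGUOUS) is correct only when every tied group
    would satisfy the label; if none would, it is mislabelled, and a
    partial overlap cannot be adjudicated (UNRESOLVED).
    """
    rule = rules.lookup(sample.label_species, sample.catch_area)
    if genetic.kind == "UNRESOLVED":
        return Verdict(sample.sample_id, "UNRESOLVED", None, genetic)
    if genetic.kind == "MIXED":
        return Verdict(sample.sample_id, "MISLABELLED", "mixed", genetic)
    if genetic.kind == "AMBIGUOUS":
        if genetic.groups <= rule.accept:
            return Verdict(sample.sample_id, "CORRECT", None, genetic)
        if genetic.groups.isdisjoint(rule.accept):
            return Verdict(sample.sample_id, "MISLABELLED", "ambiguous", genetic)
        return Verdict(sample.sample_id, "UNRESOLVED", "ambiguous", genetic)
    if genetic.group in rule.accept:
        return Verdict(sample.sample_id, "CORRECT", None, genetic)
    return Verdict(sample.sample_id, "MISLABELLED", "substitution", genetic)


def display_pct(numerator: int, denominator: int, digits: int = 2) -> float:
    """Percentage rounded half-up to ``digits`` decimals for display."""
    if denominator == 0:
        raise ZeroDivisionError("empty stratum has no rate")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-digits)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Stratum:
    n: int
    n_mislabelled: int
    n_unresolved: int = 0

    def __post_init__(self):
        if self.n_mislabelled > self.n:
            raise ValueError("mislabelled count exceeds stratum size")

    @property
    def fraction(self) -> float:
        return self.n_mislabelled / self.n

    @property
    def pct(self) -> float:
        return display_pct(self.n_mislabelled, self.n)


@dataclass
class MislabellingSummary:
    overall: Stratum
    by_label: dict[str, Stratum]
    by_level: dict[int, Stratum]


def summarize(
    verdicts: Sequence[Verdict], samples: Sequence[SampleRecord]
) -> MislabellingSummary:
    """Stratified mislabelling counts and rates.

    Denominators count samples with a resolved verdict; UNRESOLVED
    samples are tallied separately and excluded from rates.  Empty
    strata are absent from the output rather than reported as 0%.
    """
    by_id = {s.sample_id: s for s in samples}
    missing = [v.sample_id for v in verdicts if v.sample_id not in by_id]
    if missing:
        raise KeyError(f"verdicts without sample records: {missing[:5]}")

    def tally(pairs: Iterable[tuple[SampleRecord, Verdict]]) -> Stratum | None:
        n = bad = unresolved = 0
        for _, v in pairs:
            if v.verdict == "UNRESOLVED":
                unresolved += 1
                continue
            n += 1
            bad += v.verdict == "MISLABELLED"
        if n + unresolved == 0:
            return None
        return Stratum(n=n, n_mislabelled=bad, n_unresolved=unresolved)

    paired = [(by_id[v.sample_id], v) for v in verdicts]
    overall = tally(paired)
    if overall is None:
        overall = Stratum(0, 0, 0)
    labels = sorted({s.label_species for s, _ in paired})
    by_label = {
        lab: st
        for lab in labels
        if (st := tally((s, v) for s, v in paired if s.label_species == lab))
    }
    by_level = {
        lvl: st
        for lvl in sorted({s.processing_level for s, _ in paired})
        if (st := tally((s, v) for s, v in paired if s.processing_level == lvl))
    }
    return MislabellingSummary(overall=overall, by_label=by_label, by_level=by_level)


def excess_landings(
    rate: float, reference_landings: float, quota: float | None = None
) -> dict[str, float]:
    """Extrapolate a mislabelling rate to excess landings in tonnes.

    ``excess = rate * reference_landings``; when a quota is given the
    excess is also expressed as a percentage of it.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if reference_landings < 0 or (quota is not None and quota <= 0):
        raise ValueError("landings must be >= 0 and quota > 0")
    out = {"excess_tonnes": rate * reference_landings}
    if quota is not None:
        out["pct_of_quota"] = 100.0 * out["excess_tonnes"] / quota
    return out


def binomial_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a proportion."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class Table2Fixture:
    """The survey's mislabelled products plus stratum totals."""

    rows: pd.DataFrame
    totals: dict

    @property
    def samples(self) -> list[SampleRecord]:
        return [
            SampleRecord(
                sample_id=str(r.sample_id),
                label_species=r.label_species,
                catch_area=r.catch_area,
                processing_level=int(r.processing_level),
            )
            for r in self.rows.itertuples()
        ]

    @property
    def reconciled(self) -> dict[str, ReconciledID]:
        out = {}
        for r in self.rows.itertuples():
            sid = str(r.sample_id)
            g1 = taxa.group_of(r.seq_id_1)
            g2 = taxa.group_of(r.seq_id_2)
            if g1 == g2:
                out[sid] = ReconciledID(sid, "GROUP", frozenset({g1}))
            else:
                out[sid] = ReconciledID(
                    sid, "MIXED", frozenset({g1, g2}), ("replicate-disagreement",)
                )
        return out


def load_table2_fixture() -> Table2Fixture:
    """Load the packaged mislabelled-sample fixture (checksum verified)."""
    data = resources.files("fishauth.data")
    raw = data.joinpath("table2_mislabelled.tsv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE2_SHA256:
        raise ValueError(
            f"table2 fixture checksum mismatch: {digest} != {_TABLE2_SHA256}"
        )
    rows = pd.read_csv(
        pd.io.common.BytesIO(raw), sep="\t", dtype={"sample_id": str}, keep_default_na=False
    )
    if len(rows) != 21:
        raise ValueError(f"expected 21 fixture rows, found {len(rows)}")
    totals = json.loads(data.joinpath("table2_totals.json").read_text())
    return Table2Fixture(rows=rows, totals=totals)


def summarize_fixture(
    fixture: Table2Fixture | None = None, rules: RuleTable | None = None
) -> dict[str, dict]:
    """Reproduce the survey's rate table from the packaged fixture.

    Verdicts for the mislabelled rows are recomputed through the rule
    table (every row must come out MISLABELLED); denominators come from
    the fixture's stratum totals.  Returns named strata, each with
    numerator, denominator, raw fraction and display percentage.
    """
    fixture = fixture or load_table2_fixture()
    rules = rules or default_rules()
    reconciled = fixture.reconciled
    samples = fixture.samples
    verdicts = {
        s.sample_id: congruence_verdict(s, reconciled[s.sample_id], rules)
        for s in samples
    }
    not_mislabelled = [sid for sid, v in verdicts.items() if v.verdict != "MISLABELLED"]
    if not_mislabelled:
        raise AssertionError(
            f"fixture rows did not reproduce as mislabelled: {not_mislabelled}"
        )

    totals = fixture.totals
    n_all = totals["samples_analysable"]
    labels = totals["label_counts"]
    levels = totals["processing_level_counts"]
    by_sid = {s.sample_id: s for s in samples}

    def count(pred) -> int:
        return sum(1 for s in samples if pred(s, reconciled[s.sample_id]))

    def entry(k: int, n: int, digits: int = 2) -> dict:
        return {
            "numerator": k,
            "denominator": n,
            "fraction": k / n,
            "pct": display_pct(k, n, digits),
        }

    n_mis = len(samples)
    cod = lambda s: s.label_species == "Cod"
    haddock = lambda s: s.label_species == "Haddock"
    out = {
        "overall": entry(n_mis, n_all),
        "correct": entry(n_all - n_mis, n_all),
        "cod": entry(count(lambda s, g: cod(s)), labels["Cod"]),
        "cod_mixed": entry(
            count(lambda s, g: cod(s) and g.kind == "MIXED"), labels["Cod"]
        ),
        "atlantic_cod_as_pacific": entry(
            count(
                lambda s, g: cod(s)
                and s.catch_area == "Atlantic"
                and g.kind == "GROUP"
                and g.group == "macrocephalus-group"
            ),
            labels["Cod|Atlantic"],
            digits=1,
        ),
        "haddock": entry(count(lambda s, g: haddock(s)), labels["Haddock"]),
        "haddock_as_atlantic_cod": entry(
            count(lambda s, g: haddock(s) and g.kind == "GROUP" and g.group == "morhua"),
            labels["Haddock"],
        ),
        "haddock_mixed": entry(
            count(lambda s, g: haddock(s) and g.kind == "MIXED"), labels["Haddock"]
        ),
        "hake": entry(
            count(lambda s, g: s.label_species.startswith("Hake")),
            labels["Hake (M. capensis)"],
        ),
        "alaskan_pollack": entry(
            count(lambda s, g: s.label_species == "Alaskan Pollack"),
            labels["Alaskan Pollack"],
        ),
    }
    for lvl_str, n_lvl in levels.items():
        lvl = int(lvl_str)
        k = sum(1 for s in samples if s.processing_level == lvl)
        digits = 1 if lvl in (1, 5) else 2
        out[f"level_{lvl}"] = entry(k, n_lvl, digits)
    return out
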