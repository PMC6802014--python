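"""Prevalence tabulations and summary tables for resolved cohorts.

Percentages are reported on two denominators — all specimens and infected
specimens — because prevalence statements in endosymbiont surveys mix both
("83% of beetles infected" vs "72% of infections are double").  Display
rounding is half-away-from-zero to one decimal; raw fractions are preserved
alongside.

The one specimen whose mixture is evident (double-level infection) but whose
ST pair could not be read counts as infected and as a double infection, while
its STs stay unattributed: per-ST carrier counts cover only specimens with a
resolved ST assignment.  Mosaic variants (e.g. a chimeric-allele ST named
``<parent>r``) are tallied as their own carriers, not folded into the parent
ST.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from wolcall.coinfection import AMBIGUOUS, DOUBLE, SINGLE, UNINFECTED, SpecimenRecord


def display_percent(fraction: float) -> float:
    """Round a fraction to one decimal of percent, half away from zero.

    Goes through the decimal string representation so that e.g. 0.0715
    rounds to 7.2 rather than tripping over its binary approximation.
    """
    return float(
        (Decimal(repr(fraction)) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class PrevalenceSummary:
    """Integer counts and both-denominator percentages for one cohort."""

    n_total: int
    n_uninfected: int
    n_single: int
    n_double: int
    n_ambiguous: int  # infected, level known, STs unresolved
    st_carriers: dict[str, int] = field(default_factory=dict)
    group_carriers: dict[str, int] = field(default_factory=dict)
    by_taxon: dict[str, Counter] = field(default_factory=dict)
    by_region: dict[str, Counter] = field(default_factory=dict)

    @property
    def n_infected(self) -> int:
        return self.n_single + self.n_double + self.n_ambiguous

    @property
    def n_double_level(self) -> int:
        """Double infections including ambiguous ones with mixture evidence."""
        return self.n_double + self.n_ambiguous

    def pct_of_total(self, count: int) -> float:
        return display_percent(count / self.n_total) if self.n_total else 0.0

    def pct_of_infected(self, count: int) -> float:
        return display_percent(count / self.n_infected) if self.n_infected else 0.0


def _require_resolved(records: Sequence[SpecimenRecord]) -> None:
    unresolved = [r.specimen_id for r in records if r.infection is None]
    if unresolved:
        raise ValueError(f"records not resolved: {unresolved[:5]} ...")


def tabulate_prevalence(
    records: Sequence[SpecimenRecord],
    st_groups: Mapping[str, str] | None = None,
) -> PrevalenceSummary:
    """Count infection levels, per-ST carriers and per-group carriers.

    A specimen carrying an ST alone or in combination counts once for that
    ST; group carriers count specimens carrying at least one ST of a group
    (``st_groups`` maps ST id to group; ids following the ``wCall<G><n>``
    convention are understood without it).  Ambiguous specimens (unresolved
    ST pair) count as infected at double level but contribute to no ST or
    group tally.
    """
    _require_resolved(records)

    def group_of(st_id: str) -> str:
        if st_groups and st_id in st_groups:
            return st_groups[st_id]
        if st_id.startswith("wCall") and len(st_id) > 5:
            return st_id[:6]
        return "?"

    status = Counter(r.infection.status for r in records)
    st_carriers: Counter = Counter()
    group_carriers: Counter = Counter()
    by_taxon: dict[str, Counter] = {}
    by_region: dict[str, Counter] = {}
    for r in records:
        inf = r.infection
        for st_id in set(inf.sts):
            st_carriers[st_id] += 1
        for group in {group_of(st_id) for st_id in inf.sts}:
            group_carriers[group] += 1
        by_taxon.setdefault(r.taxon, Counter())[inf.status] += 1
        if r.region:
            by_region.setdefault(r.region, Counter())[inf.status] += 1
    return PrevalenceSummary(
        n_total=len(records),
        n_uninfected=status.get(UNINFECTED, 0),
        n_single=status.get(SINGLE, 0),
        n_double=status.get(DOUBLE, 0),
        n_ambiguous=status.get(AMBIGUOUS, 0),
        st_carriers=dict(st_carriers),
        group_carriers=dict(group_carriers),
        by_taxon=by_taxon,
        by_region=by_region,
    )


def unisexual_breakdown(
    records: Sequence[SpecimenRecord], unisexual_taxa: Iterable[str]
) -> dict[str, tuple[int, int, float]]:
    """Infection composition of the unisexual species.

    Returns, over specimens of the named taxa, the count, denominator and
    percentage for: uninfected, sole-wCallA1, wCallA1+wCallC1 and
    wCallA1+wCallB1 categories (the only infection states unisexual
    *Calligrapha* showed), plus any other observed state under ``other``.
    """
    taxa = set(unisexual_taxa)
    known = {r.taxon for r in records}
    unknown = taxa - known
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    subset = [r for r in records if r.taxon in taxa]
    _require_resolved(subset)
    n = len(subset)
    counts = Counter()
    for r in subset:
        inf = r.infection
        if inf.status == UNINFECTED:
            counts["uninfected"] += 1
        elif inf.sts == ("wCallA1",):
            counts["wCallA1 alone"] += 1
        elif set(inf.sts) == {"wCallA1", "wCallC1"}:
            counts["wCallA1+wCallC1"] += 1
        elif set(inf.sts) == {"wCallA1", "wCallB1"}:
            counts["wCallA1+wCallB1"] += 1
        else:
            counts["other"] += 1
    return {
        key: (counts.get(key, 0), n, display_percent(counts.get(key, 0) / n) if n else 0.0)
        for key in ("uninfected", "wCallA1 alone", "wCallA1+wCallC1", "wCallA1+wCallB1", "other")
    }


def per_locus_allele_counts(
    sts: Iterable, include_mosaic: bool = False
) -> dict[str, int]:
    """Distinct allele ids per locus across a collection of ST profiles."""
    from wolcall.mlst import LOCUS_NAMES

    seen: dict[str, set] = {locus: set() for locus in LOCUS_NAMES}
    for st in sts:
        if not include_mosaic and st.provenance == "mosaic":
            continue
        for locus in LOCUS_NAMES:
            seen[locus].add(st.profile[locus])
    return {locus: len(ids) for locus, ids in seen.items()}


def format_summary(summary: PrevalenceSummary) -> str:
    """Human-readable prevalence report (stable, locale-independent)."""
    lines = [
        f"specimens\t{summary.n_total}",
        f"uninfected\t{summary.n_uninfected}\t{summary.pct_of_total(summary.n_uninfected)}%",
        f"infected\t{summary.n_infected}\t{summary.pct_of_total(summary.n_infected)}%",
        f"single\t{summary.n_single}\t{summary.pct_of_infected(summary.n_single)}% of infected",
        (
            f"double\t{summary.n_double_level}\t"
            f"{summary.pct_of_infected(summary.n_double_level)}% of infected"
            + (
                f" (incl. {summary.n_ambiguous} with unresolved ST pair)"
                if summary.n_ambiguous
                else ""
            )
        ),
    ]
    for st_id in sorted(summary.st_carriers):
        count = summary.st_carriers[st_id]
        lines.append(
            f"carrier\t{st_id}\t{count}\t{summary.pct_of_infected(count)}% of infected\t"
            f"{summary.pct_of_total(count)}% of all"
        )
    for group in sorted(summary.group_carriers):
        count = summary.group_carriers[group]
        lines.append(f"group\t{group}\t{count}\t{summary.pct_of_infected(count)}% of infected")
    for taxon in sorted(summary.by_taxon):
        c = summary.by_taxon[taxon]
        lines.append(
            f"taxon\t{taxon}\t{sum(c.values())}\t"
            + ",".join(f"{k}={c[k]}" for k in sorted(c))
        )
    return "\n".join(lines) + "\n"
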