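"""Permutation chi-square contingency tests of infection against host structure.

Infection states are encoded as categorical variables under several coding
schemes (infection level; strain-group combination; specific genotype
combination; each optionally including the uninfected class), then
cross-tabulated against host categories — the immediate subclades of each
clade of a nested mtDNA hierarchy, or nuclear (*Wg*) genotypes — and tested
with a permutation chi-square: the observed Pearson statistic is compared
with its distribution under random relabelling, which conditions on both
margins and needs no large-sample approximation.

p-values use the add-one Monte-Carlo estimator p = (1 + #{X*_i >= X}) /
(1 + n_perm), which is never zero and is exact in expectation under the null.
Significance tiers are reported at .05/.01/.001 without multiple-testing
correction (a Bonferroni helper is provided but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from wolcall.coinfection import AMBIGUOUS, DOUBLE, SINGLE, UNINFECTED, SpecimenRecord
from wolcall.network import NestedCladeHierarchy

#: Coding schemes: name -> (axis, include_uninfected).
SCHEMES: dict[str, bool] = {
    "infection_level": True,
    "level_and_group": True,
    "group": False,
    "genotype_with_uninfected": True,
    "genotype": False,
    "level_and_genotype_with_uninfected": True,
    "level_and_genotype": False,
}

#: Schemes for the nuclear-marker association tests.
WG_SCHEMES = ("wg_level", "wg_genotype")


@dataclass(frozen=True)
class CodingScheme:
    name: str
    include_uninfected: bool

    @classmethod
    def by_name(cls, name: str) -> "CodingScheme":
        if name in SCHEMES:
            return cls(name, SCHEMES[name])
        if name in WG_SCHEMES:
            return cls(name, name.endswith("level"))
        raise KeyError(f"unknown coding scheme {name!r}")


class UnresolvedRecordError(ValueError):
    """A record without a resolved infection under strict encoding."""


def _group_label(record: SpecimenRecord, st_groups: Mapping[str, str]) -> str | None:
    groups = sorted({st_groups[st][-1] if st in st_groups else "?" for st in record.infection.sts})
    return "+".join(groups) if groups else None


def encode(
    records: Sequence[SpecimenRecord],
    scheme: CodingScheme | str,
    st_groups: Mapping[str, str] | None = None,
    strict: bool = False,
) -> tuple[list[str | None], list[str]]:
    """Encode each record under a coding scheme.

    Returns ``(labels, excluded)`` where ``labels[i]`` is the category of
    record *i* or ``None`` if the scheme excludes it, and ``excluded`` notes
    why records were left out.  Group labels join the groups of the carried
    STs (e.g. ``"A+C"``); genotype labels join the ST ids (``"wCallA1+
    wCallC1"``).  Ambiguous records keep their observed infection level but
    are excluded from group/genotype schemes (their STs are unknown).
    """
    if isinstance(scheme, str):
        scheme = CodingScheme.by_name(scheme)
    st_groups = dict(st_groups or {})
    labels: list[str | None] = []
    excluded: list[str] = []
    for r in records:
        if r.infection is None:
            if strict:
                raise UnresolvedRecordError(f"{r.specimen_id} has no resolved infection")
            labels.append(None)
            excluded.append(f"{r.specimen_id}: unresolved")
            continue
        inf = r.infection
        level = DOUBLE if inf.status == AMBIGUOUS else inf.status
        if inf.status == UNINFECTED and not scheme.include_uninfected:
            labels.append(None)
            excluded.append(f"{r.specimen_id}: uninfected")
            continue

        if scheme.name == "infection_level":
            labels.append(level)
            continue
        if scheme.name in ("wg_level", "wg_genotype"):
            # the Wolbachia-side variable of the Wg tests
            if scheme.name == "wg_level":
                labels.append(level)
            else:
                if inf.status == AMBIGUOUS:
                    labels.append(None)
                    excluded.append(f"{r.specimen_id}: ambiguous STs")
                elif inf.status == UNINFECTED:
                    labels.append(UNINFECTED)
                else:
                    labels.append("+".join(inf.sts))
            continue

        if inf.status == UNINFECTED:
            labels.append(UNINFECTED)
            continue
        if inf.status == AMBIGUOUS:
            labels.append(None)
            excluded.append(f"{r.specimen_id}: ambiguous STs")
            continue
        if scheme.name in ("group", "level_and_group"):
            base = _group_label(r, st_groups) or "?"
            # the level prefix separates e.g. single-A from double A+A hosts
            labels.append(f"{level}:{base}" if scheme.name == "level_and_group" else base)
        elif scheme.name in ("level_and_genotype", "level_and_genotype_with_uninfected"):
            labels.append(f"{level}:" + "+".join(inf.sts))
        else:  # genotype schemes
            labels.append("+".join(inf.sts))
    return labels, excluded


# --------------------------------------------------------------------------
# Test machinery
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyResult:
    """One permutation chi-square test of two categorical vectors."""

    clade_label: str
    scheme: str
    n: int
    statistic: float
    p_value: float
    n_perm: int
    dims: tuple[int, int]
    degenerate: bool = False

    @property
    def significance(self) -> str:
        """Star tiers at .05/.01/.001 (``"ns"`` otherwise)."""
        if self.degenerate:
            return "ns"
        if self.p_value <= 0.001:
            return "***"
        if self.p_value <= 0.01:
            return "**"
        if self.p_value <= 0.05:
            return "*"
        return "ns"


@dataclass
class BatteryReport:
    """All contingency results over a nested hierarchy plus skip log."""

    results: list[ContingencyResult] = field(default_factory=list)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)  # clade, scheme, reason

    def summary_by_level(self, alpha: float = 0.05) -> dict[str, tuple[int, int, float]]:
        """Per hierarchy level: (significant, tested, fraction significant)."""
        per_level: dict[str, list[ContingencyResult]] = {}
        for res in self.results:
            level = res.clade_label.split("-")[0]
            per_level.setdefault(level, []).append(res)
        out = {}
        for level, results in sorted(per_level.items()):
            sig = sum(1 for r in results if not r.degenerate and r.p_value <= alpha)
            out[level] = (sig, len(results), sig / len(results) if results else 0.0)
        return out


def pearson_chi2(table: np.ndarray) -> float:
    """Pearson's X² = Σ (O−E)²/E with margin-based expectations.

    The table must already be pruned of all-zero rows and columns; a 1×k or
    k×1 table is degenerate and scores 0.
    """
    table = np.asarray(table, dtype=float)
    if table.sum() < 1:
        raise ValueError("empty contingency table")
    if table.ndim != 2 or min(table.shape) < 2:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def _prune(table: np.ndarray) -> np.ndarray:
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return table


def crosstab(labels_a: Sequence, labels_b: Sequence) -> np.ndarray:
    """Dense contingency table of two equal-length label vectors."""
    cat_a = sorted(set(labels_a))
    cat_b = sorted(set(labels_b))
    idx_a = {c: i for i, c in enumerate(cat_a)}
    idx_b = {c: i for i, c in enumerate(cat_b)}
    table = np.zeros((len(cat_a), len(cat_b)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b, strict=True):
        table[idx_a[a], idx_b[b]] += 1
    return table


def permutation_test(
    labels_a: Sequence,
    labels_b: Sequence,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    clade_label: str = "",
    scheme: str = "",
) -> ContingencyResult:
    """Permutation chi-square test of independence of two label vectors.

    One vector is permuted uniformly ``n_perm`` times; the p-value is the
    add-one estimator over permutations whose statistic reaches the observed
    one.  A vector with a single category is degenerate: statistic 0, p = 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    n = len(labels_a)
    if n < 2:
        raise ValueError("need at least two observations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    codes_a = np.unique(np.asarray(labels_a, dtype=object), return_inverse=True)[1]
    codes_b = np.unique(np.asarray(labels_b, dtype=object), return_inverse=True)[1]
    n_a, n_b = codes_a.max() + 1, codes_b.max() + 1
    if n_a < 2 or n_b < 2:
        return ContingencyResult(
            clade_label, scheme, n, 0.0, 1.0, n_perm, (int(n_a), int(n_b)),
            degenerate=True,
        )

    def stat(perm_b: np.ndarray) -> float:
        flat = np.bincount(codes_a * n_b + perm_b, minlength=n_a * n_b)
        return pearson_chi2(_prune(flat.reshape(n_a, n_b)))

    observed = stat(codes_b)
    hits = 0
    for _ in range(n_perm):
        hits += stat(rng.permutation(codes_b)) >= observed - 1e-12
    p = (1 + hits) / (1 + n_perm)
    table = _prune(np.bincount(codes_a * n_b + codes_b, minlength=n_a * n_b).reshape(n_a, n_b))
    return ContingencyResult(
        clade_label, scheme, n, observed, p, n_perm, tuple(table.shape)
    )


def run_battery(
    records: Sequence[SpecimenRecord],
    hierarchy: NestedCladeHierarchy,
    schemes: Iterable[str] = tuple(SCHEMES),
    n_perm: int = 9999,
    seed: int = 0,
    st_groups: Mapping[str, str] | None = None,
) -> BatteryReport:
    """Run the full nested-clade contingency battery.

    For the whole dataset the host axis is membership in the top-level
    clades; within each clade at each level, the host axis is the immediate
    child clade (one level down) of each record's haplotype.  Every (clade,
    scheme) pair with observations on both axes is tested; degenerate cells
    (a single subclade, or a single infection category) are recorded as
    skipped.  Seeds for individual tests are spawned deterministically from
    ``seed`` in a fixed order, so the whole report is reproducible.
    """
    missing = sorted(
        {r.cox1_haplotype for r in records} - set(map(str, hierarchy.items))
    )
    if missing:
        raise ValueError(f"haplotypes absent from hierarchy: {missing}")

    report = BatteryReport()
    top = hierarchy.n_levels - 1
    schemes = list(schemes)
    encoded = {s: encode(records, s, st_groups=st_groups)[0] for s in schemes}

    jobs: list[tuple[str, int, list[int]]] = []  # clade label, child level, record idx
    # the whole-dataset test partitions by the highest level that still
    # distinguishes clades
    total_level = next(
        (k for k in range(top, 0, -1) if len(hierarchy.levels[k]) >= 2), top
    )
    jobs.append(("Total", total_level, list(range(len(records)))))
    for level in range(top, 0, -1):
        for label in sorted(hierarchy.levels[level]):
            members = hierarchy.levels[level][label]
            idx = [i for i, r in enumerate(records) if r.cox1_haplotype in members]
            jobs.append((label, level - 1, idx))

    seed_seq = np.random.SeedSequence(seed)
    child_seeds = iter(seed_seq.spawn(len(jobs) * len(schemes)))
    for clade_label, child_level, idx in jobs:
        for scheme in schemes:
            rng = np.random.default_rng(next(child_seeds))
            pairs = [
                (hierarchy.clade_of(records[i].cox1_haplotype, child_level), encoded[scheme][i])
                for i in idx
                if encoded[scheme][i] is not None
            ]
            if not pairs:
                report.skipped.append((clade_label, scheme, "no observations"))
                continue
            hosts, infections = zip(*pairs)
            if len(set(hosts)) < 2 or len(set(infections)) < 2:
                report.skipped.append((clade_label, scheme, "degenerate (single category)"))
                continue
            report.results.append(
                permutation_test(
                    list(hosts), list(infections), n_perm=n_perm, seed=rng,
                    clade_label=clade_label, scheme=scheme,
                )
            )
    return report


def wg_association(
    records: Sequence[SpecimenRecord],
    battery: BatteryReport | None = None,
    hierarchy: NestedCladeHierarchy | None = None,
    schemes: Iterable[str] = WG_SCHEMES,
    n_perm: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
    run_all: bool = False,
) -> list[ContingencyResult]:
    """Test Wolbachia infection against host nuclear (Wg) genotypes.

    Mirrors the survey design: run only within the clades whose
    mtDNA battery tests came out significant (unless ``run_all``), with the
    *Wg* genotype as the host axis.  Records without a Wg genotype are
    excluded (reported N is accordingly smaller).
    """
    seed_seq = np.random.SeedSequence(seed)
    targets: list[tuple[str, list[int]]] = []
    if run_all or battery is None or hierarchy is None:
        targets.append(("Total", [i for i, r in enumerate(records)]))
    else:
        significant = {
            res.clade_label for res in battery.results
            if not res.degenerate and res.p_value <= alpha
        }
        for label in sorted(significant):
            if label == "Total":
                idx = list(range(len(records)))
            else:
                level = int(label.split("-")[0])
                members = hierarchy.levels[level][label]
                idx = [
                    i for i, r in enumerate(records) if r.cox1_haplotype in members
                ]
            targets.append((label, idx))

    out: list[ContingencyResult] = []
    child_seeds = iter(seed_seq.spawn(max(1, len(targets)) * len(tuple(schemes))))
    for label, idx in targets:
        for scheme in schemes:
            rng = np.random.default_rng(next(child_seeds))
            labels, _ = encode([records[i] for i in idx], scheme)
            pairs = [
                (records[i].wg_genotype, lab)
                for i, lab in zip(idx, labels)
                if lab is not None and records[i].wg_genotype
            ]
            if not pairs:
                continue
            wg, infection = zip(*pairs)
            if len(set(wg)) < 2 or len(set(infection)) < 2:
                continue
            out.append(
                permutation_test(
                    list(wg), list(infection), n_perm=n_perm, seed=rng,
                    clade_label=label, scheme=scheme,
                )
            )
    return out


def bonferroni(results: Sequence[ContingencyResult]) -> dict[str, float]:
    """Bonferroni-adjusted p-values keyed by (clade, scheme)."""
    m = len(results)
    return {
        f"{r.clade_label}/{r.scheme}": min(1.0, r.p_value * m) for r in results
    }


def write_battery_tsv(report: BatteryReport, path: str) -> None:
    """Table-style TSV: one row per clade, one column pair per scheme."""
    import csv

    schemes = sorted({r.scheme for r in report.results})
    by_clade: dict[str, dict[str, ContingencyResult]] = {}
    n_by_clade: dict[str, int] = {}
    for r in report.results:
        by_clade.setdefault(r.clade_label, {})[r.scheme] = r
        n_by_clade[r.clade_label] = max(n_by_clade.get(r.clade_label, 0), r.n)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["clade", "N"] + [f"{s} (X2, sig)" for s in schemes])
        for clade in sorted(by_clade):
            row = [clade, n_by_clade[clade]]
            for s in schemes:
                r = by_clade[clade].get(s)
                row.append(f"{r.statistic:.4f} {r.significance}" if r else "NA")
            writer.writerow(row)
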