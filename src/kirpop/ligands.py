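"""KIR-HLA functional-interaction scoring.

HLA class I alleles are classified into KIR-ligand epitope groups (Bw4 on
HLA-A or HLA-B; A3/A11 on HLA-A; C1/C2 on HLA-C by the position-80
dimorphism; the C16 group; and the six-allele HLA-C subset bound by
full-length KIR2DS4).  Twelve receptor-ligand rules pair these epitopes
with KIR genes; an individual's interaction profile is the set of rules it
satisfies, a rule being satisfied when the receptor gene is carried with a
qualifying allele and any HLA allele bears the epitope.  Population
summaries report carrier frequencies per rule, the mean number of
interactions per individual, the activating/inhibitory split, and the
fraction of interactions mediated by HLA-C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .genotypes import HlaGenotype, KirGenotype, PopulationSample

__all__ = [
    "EPITOPES",
    "EpitopePanel",
    "InteractionRule",
    "InteractionProfile",
    "load_epitope_panel",
    "load_rules",
    "classify_hla",
    "interaction_profile",
    "population_interaction_summary",
    "activating_fraction",
]

EPITOPES = ("Bw4-A", "Bw4-B", "A3", "A11", "C1", "C2", "C16", "C-2DS4-subset")

#: epitope -> HLA locus that can carry it
_EPITOPE_SOURCE = {
    "Bw4-A": "A",
    "A3": "A",
    "A11": "A",
    "Bw4-B": "B",
    "C1": "C",
    "C2": "C",
    "C16": "C",
    "C-2DS4-subset": "C",
}


class LigandError(ValueError):
    pass


@dataclass
class EpitopePanel:
    """Family-level epitope lookup with two-field overrides."""

    hla_c_families: dict[str, str]
    hla_c_overrides: dict[str, str]
    hla_b_bw4_families: set[str]
    hla_b_overrides: dict[str, str]
    hla_a_bw4_families: set[str]
    c16_families: set[str]
    c_2ds4_subset: set[str]

    def classify(self, allele: str, override_table: dict[str, set[str]] | None = None) -> set[str]:
        """Epitope set of a two-field HLA allele (e.g. ``C*04:01``)."""
        allele = allele.strip()
        if override_table and allele in override_table:
            return set(override_table[allele])
        locus = allele.partition("*")[0]
        family = allele.partition(":")[0]
        epitopes: set[str] = set()
        if locus == "A":
            if family in self.hla_a_bw4_families:
                epitopes.add("Bw4-A")
            if family == "A*03":
                epitopes.add("A3")
            if family == "A*11":
                epitopes.add("A11")
        elif locus == "B":
            override = self.hla_b_overrides.get(allele)
            if override is not None:
                if override == "Bw4-B":
                    epitopes.add("Bw4-B")
            elif family in self.hla_b_bw4_families:
                epitopes.add("Bw4-B")
        elif locus == "C":
            c_group = self.hla_c_overrides.get(allele) or self.hla_c_families.get(family)
            if c_group not in ("C1", "C2"):
                raise LigandError(
                    f"HLA-C allele {allele!r} has no C1/C2 assignment; "
                    "extend the epitope lookup or pass an override"
                )
            epitopes.add(c_group)
            if family in self.c16_families:
                epitopes.add("C16")
            if allele in self.c_2ds4_subset:
                epitopes.add("C-2DS4-subset")
        else:
            raise LigandError(f"unrecognized HLA allele {allele!r}")
        return epitopes


def load_epitope_panel(path: str | Path | None = None) -> EpitopePanel:
    if path is None:
        with resources.files("kirpop.data").joinpath("epitope_lookup.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return EpitopePanel(
        hla_c_families=dict(raw["hla_c_families"]),
        hla_c_overrides={
            k: v for k, v in dict(raw.get("hla_c_overrides", {})).items()
        },
        hla_b_bw4_families=set(raw["hla_b_bw4_families"]),
        hla_b_overrides={
            k: ("Bw4-B" if v and v != "none" else "none")
            for k, v in dict(raw.get("hla_b_overrides", {})).items()
        },
        hla_a_bw4_families=set(raw["hla_a_bw4_families"]),
        c16_families=set(raw.get("c16_families", [])),
        c_2ds4_subset=set(raw["c_2ds4_subset"]),
    )


@dataclass(frozen=True)
class InteractionRule:
    name: str
    epitopes: tuple[str, ...]
    receptor: str
    polarity: str  # "activating" | "inhibitory"
    exclude_null: bool = False
    protein_subset: tuple[str, ...] | None = None
    count_per_epitope: bool = False

    def receptor_satisfied(self, kir: KirGenotype) -> bool:
        if kir.copies(self.receptor) < 1:
            return False
        alleles = kir.allele_list(self.receptor)
        if not alleles:
            # copy number known but alleles uncalled: subset rules cannot be
            # confirmed, plain presence rules are taken at face value
            return self.protein_subset is None
        for a in alleles:
            if self.exclude_null and a.null_flag:
                continue
            if self.protein_subset is not None and a.protein_digits not in self.protein_subset:
                continue
            return True
        return False


def load_rules(path: str | Path | None = None) -> list[InteractionRule]:
    if path is None:
        with resources.files("kirpop.data").joinpath("interaction_rules.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    rules = []
    for entry in raw["rules"]:
        rules.append(
            InteractionRule(
                name=entry["name"],
                epitopes=tuple(entry["epitopes"]),
                receptor=entry["receptor"],
                polarity=entry["polarity"],
                exclude_null=bool(entry.get("exclude_null", False)),
                protein_subset=(
                    tuple(entry["protein_subset"]) if "protein_subset" in entry else None
                ),
                count_per_epitope=bool(entry.get("count_per_epitope", False)),
            )
        )
    return rules


def classify_hla(
    allele: str,
    panel: EpitopePanel | None = None,
    override_table: dict[str, set[str]] | None = None,
) -> set[str]:
    """Epitope set of one HLA allele (see :meth:`EpitopePanel.classify`)."""
    if panel is None:
        panel = load_epitope_panel()
    return panel.classify(allele, override_table)


@dataclass
class InteractionProfile:
    """Satisfied KIR-HLA interactions of one individual."""

    individual_id: str
    satisfied: list[tuple[str, str]] = field(default_factory=list)  # (rule, epitope)

    @property
    def count(self) -> int:
        return len(self.satisfied)

    def _polarity_count(self, rules_by_name: dict[str, InteractionRule], polarity: str) -> int:
        return sum(
            1 for rule_name, _ in self.satisfied if rules_by_name[rule_name].polarity == polarity
        )

    def counts(self, rules: list[InteractionRule]) -> dict[str, int]:
        by_name = {r.name: r for r in rules}
        hla_c = sum(1 for _, epi in self.satisfied if _EPITOPE_SOURCE[epi] == "C")
        return {
            "total": self.count,
            "activating": self._polarity_count(by_name, "activating"),
            "inhibitory": self._polarity_count(by_name, "inhibitory"),
            "hla_c": hla_c,
        }


def interaction_profile(
    kir: KirGenotype,
    hla: HlaGenotype,
    rules: list[InteractionRule] | None = None,
    panel: EpitopePanel | None = None,
) -> InteractionProfile:
    """Score one individual against the interaction rule set.

    Each rule contributes at most one interaction per required epitope
    present in the individual's HLA genotype (so the C1C2 rule can add two);
    plain rules contribute at most one.
    """
    if hla is None:
        raise LigandError(f"{kir.individual_id}: missing HLA record")
    if rules is None:
        rules = load_rules()
    if panel is None:
        panel = load_epitope_panel()
    carried: set[str] = set()
    for allele in hla.all_alleles():
        carried |= panel.classify(allele)
    profile = InteractionProfile(individual_id=kir.individual_id)
    for rule in rules:
        if not rule.receptor_satisfied(kir):
            continue
        present = [e for e in rule.epitopes if e in carried]
        if not present:
            continue
        if rule.count_per_epitope:
            for e in present:
                profile.satisfied.append((rule.name, e))
        else:
            profile.satisfied.append((rule.name, present[0]))
    return profile


def activating_fraction(
    per_rule_carrier_freqs: dict[str, float],
    rules: list[InteractionRule] | None = None,
    round_to: int | None = 2,
) -> tuple[float, float]:
    """Activating and inhibitory fractions from per-rule carrier frequencies.

    Returns ``(activating, inhibitory)`` = polarity sums divided by the total
    over all rules, rounded to *round_to* decimals (None for full precision).
    """
    if rules is None:
        rules = load_rules()
    by_name = {r.name: r for r in rules}
    act = sum(f for name, f in per_rule_carrier_freqs.items() if by_name[name].polarity == "activating")
    inh = sum(f for name, f in per_rule_carrier_freqs.items() if by_name[name].polarity == "inhibitory")
    total = act + inh
    if total <= 0:
        raise LigandError("all carrier frequencies are zero; fraction undefined")
    out = (act / total, inh / total)
    if round_to is not None:
        out = (round(out[0], round_to), round(out[1], round_to))
    return out


def population_interaction_summary(
    pop: PopulationSample,
    rules: list[InteractionRule] | None = None,
    panel: EpitopePanel | None = None,
) -> dict:
    """Per-population interaction table.

    Reports, on a carrier (presence/absence) basis, the fraction of
    individuals satisfying each rule; the mean/min/max interaction count per
    individual; activating/inhibitory fractions of the carrier-frequency
    total; and the HLA-C-mediated share on both the carrier-frequency basis
    and the per-instance basis (total C-mediated interaction instances over
    all instances).
    """
    if rules is None:
        rules = load_rules()
    if panel is None:
        panel = load_epitope_panel()
    profiles = [
        interaction_profile(k, h, rules=rules, panel=panel) for k, h in pop.records
    ]
    n = len(profiles)
    carrier = {
        rule.name: sum(1 for p in profiles if any(s[0] == rule.name for s in p.satisfied)) / n
        for rule in rules
    }
    counts = [p.count for p in profiles]
    act_frac, inh_frac = activating_fraction(carrier, rules, round_to=None)
    c_rules = [r.name for r in rules if all(_EPITOPE_SOURCE[e] == "C" for e in r.epitopes)]
    total_carrier = sum(carrier.values())
    c_carrier_basis = (
        sum(carrier[name] for name in c_rules) / total_carrier if total_carrier else float("nan")
    )
    instance_totals = [p.counts(rules) for p in profiles]
    all_instances = sum(t["total"] for t in instance_totals)
    c_instances = sum(t["hla_c"] for t in instance_totals)
    return {
        "population": pop.name,
        "n": n,
        "carrier_freqs": carrier,
        "mean_interactions": float(sum(counts)) / n,
        "min_interactions": min(counts),
        "max_interactions": max(counts),
        "activating_fraction": act_frac,
        "inhibitory_fraction": inh_frac,
        "hla_c_fraction_carrier": c_carrier_basis,
        "hla_c_fraction_instance": (
            c_instances / all_instances if all_instances else float("nan")
        ),
    }
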