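"""Functional core microbiota selection.

A genus is part of the functional core when it simultaneously

  (i)   is detected stably through fermentation (non-zero abundance in at
        least a ``prevalence_fraction`` share of samples, default 90 %),
  (ii)  is highly correlated with all three flavour sets (organic acids,
        amino acids and volatiles; sugars are excluded from this logic),
  (iii) has VIP over the predictive components strictly greater than the
        VIP threshold (default 1.55), and
  (iv)  is highly correlated (|rho| above the high threshold, 0.8) with
        strictly more than ``min_flavour_count`` flavours (default 25).

All numeric criteria use strict inequality except prevalence, which is a
"at least" fraction.  The Venn summary counts genera in each of the seven
non-empty intersection regions of the three flavour sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fermlink.association import AssociationNetwork, flavour_set_membership
from fermlink.tables import AbundanceTable, SampleMetadata


class CoreSelectionError(ValueError):
    pass


@dataclass
class CoreCriteria:
    prevalence_fraction: float = 0.9
    vip_threshold: float = 1.55
    rho_threshold: float = 0.8
    min_flavour_count: int = 25


@dataclass
class CoreReport:
    """Per-genus criterion evaluations and the resulting core set."""

    records: pd.DataFrame       # per-genus intermediates + pass/fail flags
    core: tuple[str, ...]
    criteria: CoreCriteria
    venn: dict = field(default_factory=dict)

    def recompute_core(self) -> tuple[str, ...]:
        """Re-derive the core set from the stored pass/fail columns."""
        flags = self.records[["pass_prevalence", "pass_shared", "pass_vip", "pass_count"]]
        return tuple(self.records.index[flags.all(axis=1)])


def prevalence(abundance: AbundanceTable, metadata: SampleMetadata | None = None
               ) -> pd.Series:
    """Fraction of fermentation samples in which each genus is detected.

    When metadata is given, only samples with day >= 0 count (raw-material
    reference samples, marked with negative day, are excluded).
    """
    values = abundance.values
    if metadata is not None:
        aaf = metadata.table.index[metadata.table["day"].astype(float) >= 0]
        aaf = [s for s in values.columns if s in set(aaf)]
        if not aaf:
            raise CoreSelectionError("no fermentation samples (day >= 0) found")
        values = values[aaf]
    if values.shape[1] == 0:
        raise CoreSelectionError("no samples to compute prevalence over")
    return (values > 0).mean(axis=1)


def select_core(prevalence_by_genus: pd.Series, vip_by_genus: pd.Series,
                network: AssociationNetwork,
                criteria: CoreCriteria | None = None) -> CoreReport:
    """Apply the four core criteria and assemble the report.

    ``network`` must be built at the high correlation threshold
    (``criteria.rho_threshold``).  All inputs must cover the same genus
    set; a genus missing from any input is an error.
    """
    criteria = criteria or CoreCriteria()
    genera = list(prevalence_by_genus.index)
    for name, idx in (("vip", vip_by_genus.index),
                      ("network", network.genus_counts.index)):
        missing = set(genera) ^ set(idx)
        if missing:
            raise CoreSelectionError(
                f"genus set mismatch between prevalence and {name}: {sorted(missing)}"
            )
    if abs(network.threshold - criteria.rho_threshold) > 1e-12:
        raise CoreSelectionError(
            f"network threshold {network.threshold} does not match "
            f"criteria.rho_threshold {criteria.rho_threshold}"
        )
    membership = flavour_set_membership(network)
    counts = network.genus_counts["total"]
    records = pd.DataFrame({
        "prevalence": prevalence_by_genus,
        "vip": vip_by_genus.reindex(genera),
        "flavour_sets": membership["sets"].reindex(genera),
        "high_rho_count": counts.reindex(genera),
    }, index=pd.Index(genera, name="genus"))
    records["pass_prevalence"] = records["prevalence"] >= criteria.prevalence_fraction
    records["pass_shared"] = records["flavour_sets"].apply(
        lambda s: s == frozenset({"OA", "AA", "VF"})
    )
    records["pass_vip"] = records["vip"] > criteria.vip_threshold
    records["pass_count"] = records["high_rho_count"] > criteria.min_flavour_count
    flags = records[["pass_prevalence", "pass_shared", "pass_vip", "pass_count"]]
    core = tuple(records.index[flags.all(axis=1)])
    venn = venn_counts(membership["sets"])
    return CoreReport(records=records, core=core, criteria=criteria, venn=venn)


def venn_counts(sets_by_genus: pd.Series) -> dict:
    """Counts of the seven intersection regions of {OA, AA, VF}.

    Returns region counts keyed by frozenset-style labels
    (e.g. ``"OA&AA&VF"``) plus per-set totals; each total equals the sum
    of its four constituent regions.
    """
    regions = {
        "OA only": frozenset({"OA"}),
        "AA only": frozenset({"AA"}),
        "VF only": frozenset({"VF"}),
        "OA&AA": frozenset({"OA", "AA"}),
        "OA&VF": frozenset({"OA", "VF"}),
        "AA&VF": frozenset({"AA", "VF"}),
        "OA&AA&VF": frozenset({"OA", "AA", "VF"}),
    }
    counts = {name: int((sets_by_genus == members).sum())
              for name, members in regions.items()}
    totals = {}
    for s in ("OA", "AA", "VF"):
        totals[s] = int(sets_by_genus.apply(lambda m: s in m).sum())
    for s in ("OA", "AA", "VF"):
        constituent = sum(c for name, c in counts.items()
                          if s in regions[name])
        assert constituent == totals[s], "venn region bookkeeping failed"
    return {"regions": counts, "totals": totals}
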