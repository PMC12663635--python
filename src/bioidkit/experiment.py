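"""In-memory container for a spectral-count BioID experiment.

A :class:`SpectralCountExperiment` holds one run-by-prey matrix of spectral
counts together with a run manifest (which bait each run carries, whether it
is a test run or a negative control, and the cell-state condition under which
it was collected).  Preys that were not identified in a run carry an explicit
count of zero: in spectral counting "not observed" means zero spectra, not
missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = frozenset({"test", "control"})
CONDITIONS = frozenset({"cycling", "ciliated"})


class ValidationError(ValueError):
    """Raised when an experiment or its input tables violate an invariant."""


@dataclass
class SpectralCountExperiment:
    """All runs of one BioID experiment.

    Parameters
    ----------
    counts
        Integer DataFrame with one row per run (index = run identifiers)
        and one column per prey.  Zeros are materialised.
    manifest
        DataFrame indexed by run identifier with columns ``bait_id``,
        ``role`` (``test`` or ``control``) and ``condition`` (``cycling``
        or ``ciliated``).  Every counts row must have exactly one manifest
        entry.
    prey_annotations
        Optional DataFrame indexed by prey identifier with columns
        ``gene_symbol`` and (optionally) ``sequence_length``.
    """

    counts: pd.DataFrame
    manifest: pd.DataFrame
    prey_annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise ValidationError("experiment has no runs or no preys")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate run identifiers in counts")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate prey identifiers in counts")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)) or np.isnan(vals).any():
                raise ValidationError("spectral counts must be integers")
            self.counts = self.counts.astype(int)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("spectral counts must be non-negative")
        missing = {"bait_id", "role", "condition"} - set(self.manifest.columns)
        if missing:
            raise ValidationError(f"manifest lacks columns: {sorted(missing)}")
        if self.manifest.index.has_duplicates:
            raise ValidationError("run appears more than once in bait manifest")
        unknown = set(self.counts.index) - set(self.manifest.index)
        if unknown:
            raise ValidationError(
                f"runs missing from bait manifest: {sorted(unknown)}"
            )
        bad_role = set(self.manifest["role"]) - ROLES
        if bad_role:
            raise ValidationError(f"unknown run role(s): {sorted(bad_role)}")
        bad_cond = set(self.manifest["condition"]) - CONDITIONS
        if bad_cond:
            raise ValidationError(f"unknown condition(s): {sorted(bad_cond)}")
        # align manifest to counts order, dropping manifest-only runs
        self.manifest = self.manifest.loc[self.counts.index]

    # ------------------------------------------------------------------
    @property
    def prey_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def run_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def test_baits(self) -> list[str]:
        m = self.manifest
        return sorted(m.loc[m["role"] == "test", "bait_id"].unique())

    def runs_for(self, bait_id: str, condition: str | None = None) -> list[str]:
        """Run identifiers of the test runs for one bait (one condition if given)."""
        m = self.manifest
        sel = (m["bait_id"] == bait_id) & (m["role"] == "test")
        if condition is not None:
            sel &= m["condition"] == condition
        return list(m.index[sel])

    def conditions_for(self, bait_id: str) -> list[str]:
        m = self.manifest
        sel = (m["bait_id"] == bait_id) & (m["role"] == "test")
        return sorted(m.loc[sel, "condition"].unique())

    def control_runs(self, condition: str | None = None) -> list[str]:
        m = self.manifest
        sel = m["role"] == "control"
        if condition is not None:
            sel &= m["condition"] == condition
        return list(m.index[sel])

    def counts_for_runs(self, run_ids: list[str]) -> pd.DataFrame:
        return self.counts.loc[run_ids]

    def detected_preys(self, bait_id: str, condition: str | None = None) -> set[str]:
        """Preys with at least one nonzero count in the bait's (test) runs."""
        runs = self.runs_for(bait_id, condition)
        if not runs:
            return set()
        sub = self.counts.loc[runs]
        return set(sub.columns[(sub > 0).any(axis=0)])

    def total_counts(self) -> int:
        return int(self.counts.to_numpy().sum())

    # ------------------------------------------------------------------
    @classmethod
    def from_long(
        cls,
        interactions: pd.DataFrame,
        manifest: pd.DataFrame,
        prey_annotations: pd.DataFrame | None = None,
    ) -> "SpectralCountExperiment":
        """Build from a long table (run_id, prey_id, count); absent cells become 0."""
        dup = interactions.duplicated(subset=["run_id", "prey_id"])
        if dup.any():
            pairs = interactions.loc[dup, ["run_id", "prey_id"]].values.tolist()
            raise ValidationError(f"duplicate (run, prey) rows: {pairs[:5]}")
        wide = (
            interactions.pivot(index="run_id", columns="prey_id", values="count")
            .fillna(0)
            .astype(int)
        )
        # runs that appear only in the manifest (e.g. controls in which no
        # prey was identified) are all-implicit-zero rows
        wide = wide.reindex(index=manifest.index, fill_value=0).sort_index(axis=1)
        wide.index.name = None
        wide.columns.name = None
        return cls(counts=wide, manifest=manifest, prey_annotations=prey_annotations)
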