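"""Readers and writers for SAINT-convention tab-delimited tables.

The on-disk convention is the interaction / bait / prey triplet used by the
SAINT family of tools and the ProHits LIMS: tab-delimited, UTF-8, one header
row.  The scored-interaction table written here mirrors SAINT output columns
(per-replicate counts pipe-joined, AvgSpec, control counts, AvgP, BFDR) and
round-trips losslessly through :func:`read_scored_table`.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import pandas as pd

from .experiment import SpectralCountExperiment, ValidationError, ROLES, CONDITIONS
from .scoring import ScoredInteraction


class ParseError(ValueError):
    """A malformed line in a tab-delimited input file."""


_ROLE_ALIASES = {"t": "test", "c": "control", "test": "test", "control": "control"}


def _read_rows(path, n_fields_min: int):
    path = Path(path)
    rows = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ParseError(f"{path}: empty file (header row required)")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < n_fields_min:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least "
                    f"{n_fields_min} tab-delimited fields, got {len(row)}"
                )
            rows.append((lineno, row))
    return path, header, rows


def read_experiment(
    interaction_path, bait_path, prey_path=None
) -> SpectralCountExperiment:
    """Read a SAINT-style interaction/bait(/prey) triplet into an experiment.

    The interaction file needs columns run_id, bait_id, prey_id, count; the
    bait file run_id, bait_id, role, condition; the optional prey file
    prey_id, gene_symbol[, sequence_length].  Preys absent from a run carry
    an implicit count of zero in the resulting run-by-prey matrix.
    """
    ipath, _, irows = _read_rows(interaction_path, 4)
    if not irows:
        raise ValidationError(f"{ipath}: no interactions")
    recs = []
    for lineno, row in irows:
        run_id, bait_id, prey_id, count_s = (f.strip() for f in row[:4])
        try:
            count = int(count_s)
        except ValueError:
            raise ParseError(
                f"{ipath}: line {lineno}: spectral count {count_s!r} is not an integer"
            ) from None
        if count < 0:
            raise ParseError(f"{ipath}: line {lineno}: negative spectral count")
        recs.append((run_id, bait_id, prey_id, count))
    inter = pd.DataFrame(recs, columns=["run_id", "bait_id", "prey_id", "count"])

    bpath, _, brows = _read_rows(bait_path, 4)
    man = []
    for lineno, row in brows:
        run_id, bait_id, role, condition = (f.strip() for f in row[:4])
        role_n = _ROLE_ALIASES.get(role.lower())
        if role_n is None:
            raise ParseError(
                f"{bpath}: line {lineno}: role {role!r} not one of {sorted(ROLES)}"
            )
        if condition.lower() not in CONDITIONS:
            raise ParseError(
                f"{bpath}: line {lineno}: condition {condition!r} "
                f"not one of {sorted(CONDITIONS)}"
            )
        man.append((run_id, bait_id, role_n, condition.lower()))
    manifest = pd.DataFrame(
        man, columns=["run_id", "bait_id", "role", "condition"]
    )
    if manifest["run_id"].duplicated().any():
        dups = manifest.loc[manifest["run_id"].duplicated(), "run_id"].tolist()
        raise ValidationError(f"{bpath}: duplicate run(s) in bait manifest: {dups}")
    manifest = manifest.set_index("run_id")

    missing = set(inter["run_id"]) - set(manifest.index)
    if missing:
        raise ValidationError(
            f"runs in {ipath} missing from bait manifest: {sorted(missing)}"
        )
    # bait identity in the interaction file must agree with the manifest
    for run_id, bait_id in inter[["run_id", "bait_id"]].drop_duplicates().values:
        if manifest.loc[run_id, "bait_id"] != bait_id:
            raise ValidationError(
                f"run {run_id!r}: bait {bait_id!r} in interaction file "
                f"disagrees with manifest ({manifest.loc[run_id, 'bait_id']!r})"
            )

    annot = None
    if prey_path is not None:
        ppath, _, prows = _read_rows(prey_path, 2)
        arecs = {}
        for lineno, row in prows:
            prey_id = row[0].strip()
            if prey_id in arecs:
                raise ValidationError(f"{ppath}: duplicate prey {prey_id!r}")
            seq_len = None
            if len(row) > 2 and row[2].strip():
                try:
                    seq_len = int(row[2])
                except ValueError:
                    raise ParseError(
                        f"{ppath}: line {lineno}: sequence length not an integer"
                    ) from None
                if seq_len <= 0:
                    raise ParseError(f"{ppath}: line {lineno}: sequence length <= 0")
            arecs[prey_id] = (row[1].strip(), seq_len)
        annot = pd.DataFrame(
            {
                "gene_symbol": {k: v[0] for k, v in arecs.items()},
                "sequence_length": {k: v[1] for k, v in arecs.items()},
            }
        )
        annot.index.name = "prey_id"

    return SpectralCountExperiment.from_long(
        inter[["run_id", "prey_id", "count"]], manifest, prey_annotations=annot
    )


def write_experiment(
    experiment: SpectralCountExperiment,
    interaction_path,
    bait_path,
    prey_path=None,
    sparse: bool = True,
) -> None:
    """Write an experiment back to the triplet convention.

    With ``sparse=True`` (default) zero-count cells are left implicit, the
    SAINT convention; the matching reader re-materialises them.
    """
    long = (
        experiment.counts.stack()
        .rename("count")
        .reset_index()
        .set_axis(["run_id", "prey_id", "count"], axis=1)
    )
    if sparse:
        long = long[long["count"] > 0]
    long = long.merge(
        experiment.manifest["bait_id"], left_on="run_id", right_index=True
    )
    with Path(interaction_path).open("w", encoding="utf-8") as fh:
        fh.write("run_id\tbait_id\tprey_id\tcount\n")
        for r in long.itertuples(index=False):
            fh.write(f"{r.run_id}\t{r.bait_id}\t{r.prey_id}\t{r.count}\n")
    with Path(bait_path).open("w", encoding="utf-8") as fh:
        fh.write("run_id\tbait_id\trole\tcondition\n")
        for run_id, row in experiment.manifest.iterrows():
            fh.write(f"{run_id}\t{row.bait_id}\t{row.role}\t{row.condition}\n")
    if prey_path is not None:
        with Path(prey_path).open("w", encoding="utf-8") as fh:
            fh.write("prey_id\tgene_symbol\tsequence_length\n")
            annot = experiment.prey_annotations
            for prey in experiment.prey_ids:
                if annot is not None and prey in annot.index:
                    sym = annot.loc[prey, "gene_symbol"]
                    sl = annot.loc[prey, "sequence_length"]
                    sl = "" if sl is None or (isinstance(sl, float) and math.isnan(sl)) else int(sl)
                else:
                    sym, sl = prey, ""
                fh.write(f"{prey}\t{sym}\t{sl}\n")


# ----------------------------------------------------------------------
# scored-interaction tables

_SCORED_COLUMNS = [
    "Bait",
    "Condition",
    "Prey",
    "Spec",
    "AvgSpec",
    "CtrlCounts",
    "CtrlAvg",
    "Prob",
    "AvgP",
    "BFDR",
]


def _fmt(x: float) -> str:
    # repr gives the shortest decimal string that round-trips the float
    return repr(float(x))


def write_scored_table(scored: list[ScoredInteraction], path, sep: str = "\t") -> None:
    """Write scored interactions, grouped by bait and sorted by ascending BFDR."""
    if not scored:
        raise ValidationError("no scored interactions to write")
    ordered = sorted(
        scored,
        key=lambda s: (
            s.bait_id,
            s.condition or "",
            s.bfdr if not math.isnan(s.bfdr) else math.inf,
            -s.avg_p,
            s.prey_id,
        ),
    )
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(sep.join(_SCORED_COLUMNS) + "\n")
        for s in ordered:
            fh.write(
                sep.join(
                    [
                        s.bait_id,
                        s.condition or "",
                        s.prey_id,
                        "|".join(str(int(c)) for c in s.replicate_counts),
                        _fmt(s.avg_spec),
                        "|".join(str(int(c)) for c in s.ctrl_counts),
                        _fmt(s.ctrl_avg),
                        "|".join(_fmt(p) for p in s.replicate_probabilities),
                        _fmt(s.avg_p),
                        _fmt(s.bfdr),
                    ]
                )
                + "\n"
            )


def read_scored_table(path, sep: str = "\t") -> list[ScoredInteraction]:
    """Read a table written by :func:`write_scored_table`."""
    path = Path(path)
    out: list[ScoredInteraction] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header != _SCORED_COLUMNS:
            raise ParseError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_SCORED_COLUMNS):
                raise ParseError(f"{path}: line {lineno}: wrong field count")
            bait, cond, prey, spec, avgspec, ctrl, ctrlavg, prob, avgp, bfdr = row
            out.append(
                ScoredInteraction(
                    bait_id=bait,
                    prey_id=prey,
                    replicate_counts=[int(c) for c in spec.split("|") if c != ""],
                    replicate_probabilities=[
                        float(p) for p in prob.split("|") if p != ""
                    ],
                    avg_p=float(avgp),
                    avg_spec=float(avgspec),
                    ctrl_counts=[int(c) for c in ctrl.split("|") if c != ""],
                    ctrl_avg=float(ctrlavg),
                    bfdr=float(bfdr),
                    condition=cond or None,
                )
            )
    return out
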