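"""Synthetic fractionated-proteome generator.

Emulates the statistical structure of a 3-fraction (NaCl / SDS / GnHCl)
ECM extraction quantified by emPAI in a control vs treated design:
log-normal per-protein abundance, a per-protein log2-normal treatment
effect, a random (Dirichlet) split of each group's signal across extraction
fractions, and group-level dropout (a protein absent from *all* fractions
of one group), which is what produces the unique-to-one-group classes.

Everything is reproducible from an integer seed; generated tables embed
their generating spec as a ``#`` metadata header.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .proteome import ProteinRecord, records_to_frame

DEFAULT_FRACTIONS = ("nacl", "sds", "gnhcl")
DEFAULT_GROUPS = ("control", "ccl4")


@dataclasses.dataclass(frozen=True)
class ProteomeSpec:
    """Generating parameters for a synthetic two-group proteome.

    Defaults emulate the fixture study's conditions: emPAI spread of a few
    orders of magnitude (log-normal, sigma 1.2 in natural log), molecular
    weights spanning the small-glycoprotein-to-collagen range, a symmetric
    treatment effect (log2 mean 0, sd 1), and mild group-level dropout that
    is heavier in the control group (~7% vs ~1%, the ratio behind the
    observed excess of treatment-unique proteins).
    """

    n_proteins: int = 100
    fractions: tuple[str, ...] = DEFAULT_FRACTIONS
    groups: tuple[str, ...] = DEFAULT_GROUPS
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 1.2
    fold_change_log2_mean: float = 0.0
    fold_change_log2_sd: float = 1.0
    zero_prob_control: float = 0.07
    zero_prob_treatment: float = 0.01
    mw_range: tuple[float, float] = (15.0, 300.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        for p in (self.zero_prob_control, self.zero_prob_treatment):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"dropout probability {p} outside [0, 1]")
        if self.abundance_log_sd < 0 or self.fold_change_log2_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if len(self.groups) != 2:
            raise ValidationError("exactly two groups (control, treatment) expected")
        if not self.mw_range[0] > 0 or self.mw_range[1] < self.mw_range[0]:
            raise ValidationError(f"invalid mw_range {self.mw_range}")


def generate_proteome(spec: ProteomeSpec) -> list[ProteinRecord]:
    """Draw one synthetic proteome; fully reproducible from ``spec.seed``.

    Per protein: molecular weight uniform in ``mw_range``; control-group
    total emPAI log-normal; treatment total = control × 2^(effect draw);
    each group total split across fractions by an independent Dirichlet(1,1,1)
    partition; dropout applied independently per group at the group level.
    """
    rng = np.random.default_rng(spec.seed)
    control, treatment = spec.groups
    n = spec.n_proteins
    mw = rng.uniform(*spec.mw_range, size=n)
    base = np.exp(rng.normal(spec.abundance_log_mean, spec.abundance_log_sd, size=n))
    effect = rng.normal(spec.fold_change_log2_mean, spec.fold_change_log2_sd, size=n)
    totals = {control: base, treatment: base * np.exp2(effect)}
    dropout_p = {control: spec.zero_prob_control, treatment: spec.zero_prob_treatment}
    records: list[ProteinRecord] = []
    for i in range(n):
        pid = f"SYN{i:04d}"
        for group in spec.groups:
            dropped = rng.random() < dropout_p[group]
            shares = rng.dirichlet(np.ones(len(spec.fractions)))
            if dropped:
                continue
            for fraction, share in zip(spec.fractions, shares):
                records.append(
                    ProteinRecord(
                        protein_id=pid,
                        mw_kda=float(mw[i]),
                        group=group,
                        fraction=fraction,
                        empai=float(totals[group][i] * share),
                    )
                )
    return records


def write_proteome(
    records: list[ProteinRecord], path: str | Path, spec: ProteomeSpec
) -> None:
    """Write a generated proteome as TSV with its spec embedded as a ``#``
    header line, plus a JSON sidecar of the same metadata."""
    path = Path(path)
    meta = dataclasses.asdict(spec)
    frame = records_to_frame(records)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ecmbind synthetic proteome; spec=" + json.dumps(meta) + "\n")
        frame.to_csv(fh, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"generator": "ecmbind.synthetic", "spec": meta}, indent=2))


def table_fixtures():
    """The packaged printed-table fixtures: the 15-protein abundance table
    and the rate-parameterized ligand:receptor scenarios (both groups)."""
    from . import fixtures

    return fixtures.abundance_table(), fixtures.binding_scenarios()
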