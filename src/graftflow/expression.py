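"""Expression-matrix container shared by the whole pipeline.

An :class:`ExpressionMatrix` couples a genes x samples abundance table
(RPKM-like, non-negative) with a sample sheet describing the grafting
design: graft combination (scion/rootstock cultivar pair), tissue
(``scion`` or ``rootstock``), winter stage (``CA``, ``DW``, ``DA``) and
replicate number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("combination", "tissue", "stage", "replicate")
TISSUES = ("scion", "rootstock")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with attached sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
        All entries must be finite and non-negative.
    samples
        Sample sheet indexed by sample id with columns
        ``combination, tissue, stage, replicate``.  Every column of
        ``values`` must appear in the sheet, and the design cell
        (combination, tissue, stage, replicate) must be unique.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    stages: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet misses columns {missing}")
        unknown = set(self.values.columns) - set(self.samples.index)
        if unknown:
            raise ValueError(f"samples absent from sample sheet: {sorted(unknown)[:5]}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            raise ValueError("expression values must be non-negative")
        sheet = self.samples.loc[list(self.values.columns)]
        if sheet.duplicated(subset=list(SAMPLE_COLUMNS)).any():
            raise ValueError("(combination, tissue, stage, replicate) must be unique")
        if not self.stages:
            # preserve first-appearance order of stages in the sheet
            self.stages = tuple(dict.fromkeys(sheet["stage"]))

    # ------------------------------------------------------------------
    @property
    def combinations(self) -> tuple[str, ...]:
        sheet = self.samples.loc[list(self.values.columns)]
        return tuple(dict.fromkeys(sheet["combination"]))

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def sample_ids(
        self,
        combination: str | None = None,
        tissue: str | None = None,
        stage: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given design-cell coordinates."""
        sheet = self.samples.loc[list(self.values.columns)]
        mask = pd.Series(True, index=sheet.index)
        for col, want in (("combination", combination), ("tissue", tissue), ("stage", stage)):
            if want is not None:
                mask &= sheet[col] == want
        return list(sheet.index[mask])

    def stage_means(self, genes=None) -> pd.DataFrame:
        """Per-gene replicate means, columns (combination, tissue, stage).

        Means are taken over replicates only; the result is the raw
        material for stage profiles, flow calls and the DM statistic.
        """
        values = self.values if genes is None else self.values.loc[list(genes)]
        sheet = self.samples.loc[list(values.columns)]
        keys = [sheet["combination"], sheet["tissue"], sheet["stage"]]
        means = values.T.groupby(keys, observed=True).mean().T
        means.columns.names = ["combination", "tissue", "stage"]
        return means
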