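"""Seeded end-to-end run: simulate → screen → predict → test → intersect.

One call wires every stage together on synthetic inputs whose ground
truth mirrors the headline shape of the oleic-acid hepatocyte steatosis
study the package emulates: a 1648-row lncRNA DE table screening to 648
significant transcripts (351 up, 297 down); an anchor lncRNA
(LINC01260) whose 241-mRNA ceRNA neighbourhood shares 119 miRNAs; a
differential mRNA profile intersecting that neighbourhood at exactly 5
genes (RXRB, RNPEPL1, CD82, MADD, KLC2); a qPCR plate simulated at a
true anchor fold of 0.35; and Oil-red-O OD510 readings per treatment
group.  Every stage reports its computed result, so recovery of the
planted truth is a end-to-end check of the whole chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import simulate
from .cerna import CeRNANetwork, build_cerna_network
from .de import ScreenResult, screen_differential
from .quant import AnovaResult, GroupSummary, relative_expression, summarize_od
from .targets import TargetMap, predict_targets
from .venn import VennResult, candidate_report, intersect_profiles

__all__ = ["PipelineResult", "run_pipeline", "ANCHOR_ID", "PARTNER_GENES"]

ANCHOR_ID = "LINC01260"
#: The five network mRNAs planted as differentially expressed
#: (three down, two up, matching their qPCR directions in the study design).
PARTNER_GENES = ("RXRB", "RNPEPL1", "CD82", "MADD", "KLC2")
_PARTNER_DOWN = ("RXRB", "RNPEPL1", "CD82")
_PARTNER_UP = ("MADD", "KLC2")

#: OD510 per-group (mean, sd) used by the simulator.
OD_GROUPS: Mapping[str, tuple[float, float]] = {
    "control": (0.22, 0.028),
    "OA": (0.51, 0.02),
    "OA+vector": (0.48, 0.013),
    "OA+LINC01260": (0.42, 0.01),
}


@dataclass
class PipelineResult:
    """Everything the end-to-end run computed, stage by stage."""

    seed: int
    lnc_de_table: pd.DataFrame
    screen: ScreenResult
    targetmap: TargetMap
    network: CeRNANetwork
    mrna_de_table: pd.DataFrame
    mrna_screen: ScreenResult
    venn: VennResult
    candidates: pd.DataFrame
    discrepancies: dict[str, list[str]]
    qpcr: pd.DataFrame
    anchor_fold: float
    od_summaries: list[GroupSummary]
    od_test: AnovaResult

    def summary(self) -> str:
        od = {s.group: s for s in self.od_summaries}
        lines = [
            "ceRNA pipeline summary",
            f"  seed: {self.seed}",
            f"  lncRNA DE screen: {self.screen.n_total} significant "
            f"({self.screen.n_up} up, {self.screen.n_down} down) "
            f"of {len(self.lnc_de_table)} assayed",
            f"  ceRNA network around {self.network.anchor}: "
            f"{len(self.network.edges)} mRNAs via "
            f"{len(self.network.mirna_ids)} shared miRNAs",
            f"  intersection with DE mRNA profile: {len(self.venn.both)} "
            f"candidate mRNA(s): {', '.join(self.venn.both)}",
            f"  {ANCHOR_ID} qPCR relative expression (OA vs control): "
            f"{self.anchor_fold:.3f}",
            f"  OD510 control {od['control'].mean:.3f} ± {od['control'].sd:.3f} "
            f"vs OA {od['OA'].mean:.3f} ± {od['OA'].sd:.3f} "
            f"(ANOVA p = {self.od_test.p:.2e})",
        ]
        return "\n".join(lines)


def _sub_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(
    seed: int = 0,
    n_up: int = 351,
    n_down: int = 297,
    n_null: int = 1000,
    n_partners: int = 241,
    n_mirnas: int = 300,
    n_anchor_mirnas: int = 119,
    ct_noise_sd: float = 0.2,
    n_qpcr_replicates: int = 4,
    n_od_replicates: int = 3,
) -> PipelineResult:
    """Run the full synthetic-data pipeline at the default study shape."""
    s_de, s_fix, s_mrna, s_qpcr, s_od = _sub_seeds(seed, 5)

    # 1. lncRNA DE table and screen -------------------------------------
    lnc_de, _ = simulate.generate_de_table(
        n_up, n_down, n_null, rng_seed=s_de, id_prefix="LNC",
        down_ids=(ANCHOR_ID,) if n_down else (),
    )
    screen = screen_differential(lnc_de, min_abs_log2fc=1.0, max_p=0.05)

    # 2. ceRNA neighbourhood of the anchor ------------------------------
    # every candidate shares 5 planted miRNAs with the anchor, and the
    # partner target sets jointly cover the anchor's miRNA set
    fixture = simulate.build_cerna_fixture(
        rng_seed=s_fix,
        n_mirnas=n_mirnas,
        n_anchor_mirnas=n_anchor_mirnas,
        partner_ids=list(PARTNER_GENES) + [f"CEM{i:05d}" for i in range(1, n_partners - len(PARTNER_GENES) + 1)],
        n_decoys=0,
        shared_per_partner=5,
        cover_anchor_set=True,
        anchor_id=ANCHOR_ID,
    )
    targetmap = predict_targets(
        fixture.mirnas, fixture.transcripts, min_site_type="8mer"
    )
    network = build_cerna_network(
        targetmap, anchor=ANCHOR_ID, candidate_mrnas=fixture.candidate_ids
    )

    # 3. differential mRNA profile and the Venny-style intersection -----
    mrna_de, _ = simulate.generate_de_table(
        150, 150, 400, rng_seed=s_mrna, id_prefix="MRNA",
        up_ids=_PARTNER_UP,
        down_ids=_PARTNER_DOWN,
        null_ids=[p for p in fixture.partner_ids if p not in PARTNER_GENES][:400],
    )
    mrna_screen = screen_differential(mrna_de, min_abs_log2fc=1.0, max_p=0.05)
    venn = intersect_profiles(
        network.mrna_ids,
        mrna_screen.table["lncrna_id"],
        label_a="ceRNA_network",
        label_b="DE_mRNA_profile",
    )
    candidates, discrepancies = candidate_report(venn, mrna_de, network.edges)

    # 4. qPCR validation of the anchor ----------------------------------
    plate, _ = simulate.generate_qpcr_plate(
        genes=[ANCHOR_ID, "ACTB"],
        groups=["control", "OA"],
        true_fold={(ANCHOR_ID, "OA"): 0.35},
        n_replicates=n_qpcr_replicates,
        ct_noise_sd=ct_noise_sd,
        rng_seed=s_qpcr,
    )
    folds, _excluded = relative_expression(
        plate, target_gene=ANCHOR_ID, reference_gene="ACTB",
        control_group="control",
    )
    anchor_fold = float(folds.loc[folds["group"] == "OA", "fold"].mean())

    # 5. Oil-red-O semi-quantification ----------------------------------
    od = simulate.generate_od_table(OD_GROUPS, n_replicates=n_od_replicates,
                                    rng_seed=s_od)
    od_summaries, od_test = summarize_od(od)

    return PipelineResult(
        seed=seed,
        lnc_de_table=lnc_de,
        screen=screen,
        targetmap=targetmap,
        network=network,
        mrna_de_table=mrna_de,
        mrna_screen=mrna_screen,
        venn=venn,
        candidates=candidates,
        discrepancies=discrepancies,
        qpcr=plate,
        anchor_fold=anchor_fold,
        od_summaries=od_summaries,
        od_test=od_test,
    )
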