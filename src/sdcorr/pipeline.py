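"""End-to-end orchestration of the density-correlation analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .clustering import (CopheneticResult, Dendrogram, PCAResult,
                         SilhouetteResult, cluster_areas, cophenetic_analysis,
                         pca_correlation, reorder, row_vector_distances,
                         silhouette_cut)
from .data import AnalysisConfig, CellRecord, InjectionSite, OntologyTable
from .density import (CorrelationMatrix, TPVMatrix, build_tpv,
                      correlation_matrix)
from .geometry import OverlapTable


@dataclass
class PipelineResult:
    """Everything the core analysis produces, bootstrap excluded."""

    tpv: TPVMatrix
    corr: CorrelationMatrix
    distances: pd.DataFrame
    dendrogram: Dendrogram
    reordered: pd.DataFrame
    leaf_order: list[str]
    cophenetic: CopheneticResult
    silhouette: SilhouetteResult
    pca: PCAResult


def run_pipeline(cells: Sequence[CellRecord],
                 injections: Sequence[InjectionSite],
                 ontology: OntologyTable,
                 config: AnalysisConfig,
                 overlap: OverlapTable | None = None) -> PipelineResult:
    """Counts → TPV → correlation → clustering → validation statistics.

    The multiscale bootstrap (:func:`sdcorr.clustering.au_pvalues`) is run
    separately because of its cost.
    """
    tpv = build_tpv(cells, injections, ontology, config, overlap=overlap)
    corr = correlation_matrix(tpv)
    distances = row_vector_distances(corr)
    dendro = cluster_areas(distances)
    reordered, leaf_order = reorder(corr, dendro)
    coph = cophenetic_analysis(dendro, distances)
    sil = silhouette_cut(dendro, distances)
    pca = pca_correlation(corr)
    return PipelineResult(tpv, corr, distances, dendro, reordered, leaf_order,
                          coph, sil, pca)
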