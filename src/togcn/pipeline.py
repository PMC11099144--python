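"""End-to-end single-program pipeline: matrix -> TO-GCN.

Chains the expression filter, upper-quartile normalization, replicate
collapsing, PCC computation, cutoff determination, network thresholding
and BFS leveling, so the CLI, tests and simulations share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    CoexpressionNetwork,
    PCCMatrix,
    TOGCN,
    assign_levels_bfs,
    build_gcn,
    compute_pcc_matrix,
    determine_cutoff,
)
from .expr_io import (
    ExpressionMatrix,
    SampleSheet,
    condition_means,
    filter_expressed,
    upper_quartile_normalize,
)

__all__ = ["PipelineResult", "build_togcn"]


@dataclass(frozen=True)
class PipelineResult:
    expressed: ExpressionMatrix  # filtered + normalized, sample-level
    profiles: ExpressionMatrix  # matrix the PCC was computed on
    pcc: PCCMatrix
    cutoff: float
    network: CoexpressionNetwork
    togcn: TOGCN


def build_togcn(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    tf_ids: list[str],
    seed_gene: str,
    *,
    alpha: float = 0.05,
    tpm_min: float = 1.0,
    normalize: bool = True,
    use_condition_means: bool = True,
    cutoff: float | None = None,
) -> PipelineResult:
    """Run filter -> normalize -> collapse -> PCC -> cutoff -> GCN -> BFS.

    ``cutoff`` overrides the empirical determination when given. TFs that
    do not survive the expression filter are simply absent from the
    network.
    """
    expressed = filter_expressed(matrix, tpm_min=tpm_min)
    if normalize:
        expressed = upper_quartile_normalize(expressed)
    profiles = condition_means(expressed, sheet) if use_condition_means else expressed
    tf_present = [g for g in tf_ids if g in profiles.data.index]
    if seed_gene not in tf_present:
        raise ValueError(f"seed gene {seed_gene!r} not among expressed TFs")
    pcc = compute_pcc_matrix(profiles, tf_present)
    cut = determine_cutoff(pcc, alpha=alpha) if cutoff is None else cutoff
    network = build_gcn(pcc, cut)
    togcn = assign_levels_bfs(network, seed_gene)
    return PipelineResult(expressed, profiles, pcc, cut, network, togcn)
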