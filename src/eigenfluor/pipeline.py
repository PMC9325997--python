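"""End-to-end pipeline: cube -> (Std | CLAHE) -> median -> PCA -> composite.

The two preprocessing branches are complementary and run independently —
each feeds its own PCA, and each yields its own composite.  Row
standardization emphasises within-row contrast (hard tissue and
epithelium), adaptive equalization emphasises stromal structure; a study
typically inspects both composites side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .io import SpectralCube
from .pca import EigenImageSet, RGBComposite, compose_rgb, spectral_pca
from .preprocess import PreprocessedCube, preprocess


@dataclass
class BranchResult:
    """Everything one branch produced: intermediates, eigen set, composite.

    ``composite`` is None when n_components != 3 (an RGB merge needs
    exactly three planes); the eigen set is always present.
    """

    preprocessed: PreprocessedCube
    eigen: EigenImageSet
    composite: RGBComposite | None


def run_branch(cube: SpectralCube, branch: str, config: PipelineConfig) -> BranchResult:
    pre = preprocess(
        cube,
        branch=branch,
        clahe_params=config.clahe_params,
        median_size=config.median_size,
    )
    eigen = spectral_pca(pre, n_components=config.n_components)
    composite = compose_rgb(eigen) if config.n_components == 3 else None
    return BranchResult(preprocessed=pre, eigen=eigen, composite=composite)


def run_pipeline(cube: SpectralCube, config: PipelineConfig | None = None) -> dict[str, BranchResult]:
    """Run the configured branch(es) on a spectral cube.

    Returns a mapping ``{"std": BranchResult, "clahe": BranchResult}``
    restricted to the branches the config selects.  Identical input and
    config give bit-identical composites: the solver is exact and the
    component sign rule is fixed.
    """
    if config is None:
        config = PipelineConfig()
    return {branch: run_branch(cube, branch, config) for branch in config.branches}
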