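"""coreresponse: cross-context core-response integration.

Given per-condition differential-expression tables, per-condition ChIP-seq
peak sets, a genome with its annotation, and a motif library, this package
builds the cross-condition core of responsive genes (with its direction
map and orthology projection), the core of shared chromatin regions (with
genomic categorisation and super-enhancer overlap), scans for CDX-type
binding sites and tests co-motif enrichment in their flanks against matched
random backgrounds, and validates the gene core by Fisher enrichment in
external gene lists and by driver-expression stratification of cohorts.
A synthetic-data module generates all inputs with planted, known truth.
"""

from importlib import resources

from .config import PipelineConfig, load_config, save_config
from . import io_formats, synthetic_data, deg_core, peak_core
from . import motif_analysis, enrichment_validation, pipeline

__version__ = "0.1.0"

__all__ = [
    "PipelineConfig", "load_config", "save_config", "load_cdx_pwm",
    "io_formats", "synthetic_data", "deg_core", "peak_core",
    "motif_analysis", "enrichment_validation", "pipeline",
]


def load_cdx_pwm(pseudocount: float = 1.0):
    """The packaged CDX2-type position frequency matrix.

    A synthetic matrix (the curated JASPAR entry cannot ship with the
    package) constructed so that its IUPAC consensus at the 0.25 frequency
    cut is YATAAAK, the published CDX-binding consensus T/C-A-T-A-A-A-T/G.
    """
    path = resources.files("coreresponse").joinpath(
        "data", "cdx2_synthetic.pfm")
    with resources.as_file(path) as p:
        return io_formats.read_pfm(p, pseudocount=pseudocount)
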