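"""End-to-end convenience: database build -> index -> search -> rescore -> report."""
from __future__ import annotations

import pandas as pd

from .indexer import MassIndex, build_fragment_index, build_peptide_index
from .io_app import SearchConfig
from .rescoring import filter_results, rescore_psms, results_table
from .search import CandidatePSM, SpectrumSearcher, Spectrum, search_all
from .sequence_db import PeptideDatabase, Protein, build_database


def build_indexes(targets: list[Protein], config: SearchConfig
                  ) -> tuple[PeptideDatabase, MassIndex, MassIndex]:
    """Digest targets plus reversed decoys and build both indexes."""
    db, forms = build_database(
        targets,
        enzyme=config.enzyme_rule,
        max_missed=config.max_missed,
        len_range=config.len_range,
        fixed_mods=config.fixed_mod_specs,
        variable_mods=config.variable_mod_specs,
        max_var=config.max_var,
        add_decoys=True,
    )
    return db, build_fragment_index(forms), build_peptide_index(forms)


def make_searcher(db: PeptideDatabase, frag_index: MassIndex,
                  pep_index: MassIndex, config: SearchConfig) -> SpectrumSearcher:
    return SpectrumSearcher(
        db=db, frag_index=frag_index, pep_index=pep_index,
        linker=config.linker_spec,
        frag_tol_ppm=config.fragment_tol_ppm,
        prec_tol_ppm=config.precursor_tol_ppm,
        top_k=config.top_k,
    )


def run_pipeline(targets: list[Protein], spectra: list[Spectrum],
                 config: SearchConfig | None = None, progress: bool = False
                 ) -> tuple[pd.DataFrame, list[CandidatePSM]]:
    """Search spectra against a protein set and return the FDR-filtered report
    plus the raw per-spectrum best PSMs (None entries dropped)."""
    config = config or SearchConfig()
    db, frag_index, pep_index = build_indexes(targets, config)
    searcher = make_searcher(db, frag_index, pep_index, config)
    psms = [p for p in search_all(spectra, searcher, progress=progress) if p is not None]
    rescored = rescore_psms(psms, mode=config.fdr_mode)
    kept = filter_results(rescored, fdr_threshold=config.fdr_threshold)
    return results_table(kept), psms
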