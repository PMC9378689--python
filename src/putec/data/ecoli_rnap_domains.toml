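# Curated default domain definition for E. coli RNA polymerase
# elongation complexes.
#
# CURATED DATA, NOT CODE: residue boundaries for the swivel-module
# members (clamp, shelf, jaw, SI3, beta' C-terminal region) and the core
# module are curated from the structural literature on RNAP swiveling in
# hairpin-paused and backtracked elongation complexes.  The exact
# boundaries used by any particular study are rarely printed; these
# ranges are approximate by design and users comparing specific
# depositions should override them per structure.  Angle measurements
# downstream carry a tolerance that absorbs this boundary uncertainty.
#
# Chain convention (typical for E. coli RNAP depositions):
#   A, B = alpha subunits, C = beta, D = beta', E = omega.
# Residue numbers are author numbering of the E. coli subunits.

name = "ecoli_rnap_default"

# --- swivel module (rotates as a rigid body during swiveling) --------------

[domain.clamp]
D = [[1, 342], [1318, 1344]]

[domain.shelf]
D = [[787, 931]]

[domain.jaw]
D = [[1135, 1317]]

# SI3 (beta' sequence insertion in the trigger loop, aka beta' i6)
[domain.si3]
D = [[943, 1130]]

[domain.betaprime_cterm]
D = [[1345, 1407]]

# dock moves with the swivel module but is listed separately; it is not
# one of the five members used for the residual-rotation fit by default
[domain.dock]
D = [[370, 420]]

# --- core module (the alignment reference) ---------------------------------
# beta minus its SI2 (beta i9) insertion plus the beta' mid-region
# between the dock and the shelf.

[domain.core]
C = [[10, 930], [1050, 1230]]
D = [[430, 780]]

# --- markers and probes ----------------------------------------------------

# beta' bridge helix, the axis reference for swivel geometry
[domain.bridge_helix]
D = [[770, 804]]

# beta SI2 (beta i9) lineage-specific insertion; its tip displacement
# discriminates swiveled from non-swiveled complexes
[domain.betasi2]
C = [[938, 1042]]

# beta' lid, pushed aside when the RNA-DNA hybrid lengthens
[domain.lid]
D = [[251, 264]]

# beta' zinc-binding domain at the RNA exit channel (putRNA docking site)
[domain.zbd]
D = [[55, 97]]

# beta flap tip helix region
[domain.flap_tip]
C = [[890, 914]]

# beta' clamp helices (sigma2 binding site)
[domain.clamp_helices]
D = [[264, 309]]

# beta' clamp toe
[domain.clamp_toe]
D = [[144, 179]]
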