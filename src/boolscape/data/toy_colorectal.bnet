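# Hand-built colorectal-like signaling model, 20 nodes, exhaustively
# enumerable.  Growth inputs EGF/ECM/Wnt are pinned ON (DNAdam OFF) by the
# accompanying YAML config, modelling the normal growth condition.
#
# Beta-catenin, Snail, MMP and P115RhoGEF are self-sustaining latches whose
# triggers are gated by the tumor-suppressor analogs: each driver mutation
# (APC:0 -> KRAS:1 -> PTEN:0 -> TP53:0) opens one more branch of the
# metastatic program, so the metastatic basin grows strictly with every
# stage.  The cyclin cascade is driven by beta-catenin, which makes
# beta-catenin OFF the unique single-node control restoring quiescence.

# --- tumor suppressors / oncogene analogs (constitutive when unmutated) ---
APC, 1
RasGAP, 1
PTEN, 1
TP53, 1
KRAS, EGF & !RasGAP

# --- Wnt / beta-catenin axis: latch opened by APC loss --------------------
bcatenin, bcatenin | (Wnt & !APC)

# --- metastasis program ---------------------------------------------------
Snail, Snail | (bcatenin & !PTEN)
MMP, MMP | (bcatenin & !TP53)
P115RhoGEF, P115RhoGEF | (KRAS & ECM)
Rho, P115RhoGEF & !Rho
Ecadherin, !bcatenin | !Snail

# --- cyclin cascade (cell cycle), driven by beta-catenin ------------------
CyclinD, bcatenin & !CyclinB
CyclinE, CyclinD & !CyclinB
CyclinA, CyclinE
CyclinB, CyclinA

# --- apoptosis ------------------------------------------------------------
Casp3, DNAdam & TP53
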