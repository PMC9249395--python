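# Baseline "shark" parameter set: produces a tricuspid tooth with a tall
# central primary cusp at 11,000 iterations, the embryonic catshark
# morphology.  The originating study tuned its presets inside ToothMaker
# (with developer assistance) and published them only as a supplementary
# file, with conflicting Act/Inh magnitudes quoted in the text; the
# values below are therefore this package's own calibration of its
# activator-inhibitor model to the same phenotypes:
#   baseline          -> 3 cusps
#   act x1.1 (+deg up) -> 5 cusps
#   act down / inh up  -> unicuspid, then no tooth
#   act up / inh down  -> supernumerary cusps / widened crown
act = 1.2
inh = 10.4
deg = 0.03
da = 0.01
di = 0.4
sec = 0.3
bwi = 15
bgr = 0.005
bia = 1.0
pro = 0.001
n_iter = 11000
seed = 0
# additional network constants
bas = 0.00045    # basal activator production
kap = 0.15       # autoactivation saturation
dega = 0.03      # activator turnover (deg itself is signal turnover)
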