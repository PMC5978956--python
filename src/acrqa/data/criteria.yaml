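# Default acceptance criteria, one entry per metric family.  Values follow the
# ACR-conventional bounds for the standard 5 mm protocol:
#   piu  >= 82 %          (image intensity uniformity at 3T with correction off
#                          this is the accreditation floor)
#   gr   <= 2.5 %         (|ghosting ratio|; routine systems stay well under)
#   st   nominal +- 0.7 mm (slice thickness accuracy for the 5 mm protocol)
#   sp   |displacement| <= 5 mm  (slice position accuracy on S1/S11)
#   lcd  >= 37 complete spokes of 40
#   hcsr <= 1.0 mm resolved in each in-plane direction
#   gd   |%GD| <= 1 %     (geometric distortion; ~2 mm on the 190 mm phantom;
#                          set comparator abs_dev_le with units mm for an
#                          absolute-mm bound instead)
# Comparators: ge, le, abs_le (|value| <= bound),
# abs_dev_le (|value - reference| <= bound; reference "nominal" resolves to the
# series' nominal slice thickness).
piu: {comparator: ge, bound: 82.0, units: "%"}
gr: {comparator: le, bound: 2.5, units: "%"}
st: {comparator: abs_dev_le, bound: 0.7, reference: nominal, units: "mm"}
sp: {comparator: abs_le, bound: 5.0, units: "mm"}
lcd: {comparator: ge, bound: 37, units: "spokes"}
hcsr: {comparator: le, bound: 1.0, units: "mm"}
gd: {comparator: abs_le, bound: 1.0, units: "%"}
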