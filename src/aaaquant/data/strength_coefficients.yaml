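# Noninvasive AAA wall-strength model, version 1 (statistical regression model
# from the rupture-potential-index literature the FEA pipeline builds on).
#
#   strength [N/cm^2] = intercept
#                       + ilt.coef  * (sqrt(ILT [cm]) - ilt.center)
#                       + nord.coef * (NORD - nord.center)
#                       + hist.coef * HIST
#                       + sex.coef  * SEX
#
# Covariate coding used throughout this package:
#   NORD: maximum aneurysm diameter / infrarenal neck diameter (dimensionless)
#   HIST: 1 if family history of AAA, 0 otherwise
#   SEX:  +1/2 male, -1/2 female
#   ILT:  local intraluminal thrombus thickness in cm (optional; 0 = no thrombus)
name: noninvasive-wall-strength-v1
units: N/cm^2
intercept: 71.9
ilt:
  coef: -37.9
  center: 0.81
  transform: sqrt
  default: 0.0
nord:
  coef: -15.6
  center: 2.46
hist:
  coef: -21.3
  center: 0.0
sex:
  coef: 19.3
  center: 0.0
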