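# SYNTHETIC stand-in for the Keskin et al. (1998) inter-chain contact-energy
# table (magnitudes). Deterministically generated on the MJ scale; replace with
# the published KE matrix via the custom-table loader for production use.
       A      C      D      E      F      G      H      I      K      L      M      N      P      Q      R      S      T      V      W      Y
A  2.180  2.287  1.407  1.222  3.360  1.984  2.261  3.493  1.075  3.533  2.855  1.526  1.619  1.377  1.142  1.885  1.966  3.105  3.112  2.359
C  2.287  4.282  1.941  1.904  4.452  2.355  2.777  4.080  1.594  4.350  3.429  1.962  2.457  2.212  2.249  2.078  2.525  3.980  3.875  3.052
D  1.407  1.941  0.933  0.630  2.601  0.916  1.689  2.668  1.437  2.399  2.026  1.249  0.990  1.291  1.922  1.408  1.185  1.800  2.276  2.213
E  1.222  1.904  0.630  0.676  2.710  1.069  1.573  2.372  1.337  2.690  2.012  1.155  0.728  1.128  1.741  1.263  1.168  1.944  2.272  1.906
F  3.360  4.452  2.601  2.710  5.759  3.091  3.438  4.856  2.661  5.424  4.686  2.414  3.070  2.979  3.112  2.703  3.515  4.768  4.565  4.305
G  1.984  2.355  0.916  1.069  3.091  1.752  1.560  2.929  0.821  3.055  2.529  1.452  1.425  0.909  1.252  1.416  1.467  2.278  2.595  2.291
H  2.261  2.777  1.689  1.573  3.438  1.560  1.854  3.332  0.913  3.357  2.598  1.495  1.928  1.292  1.668  1.117  2.138  2.878  2.833  2.460
I  3.493  4.080  2.668  2.372  4.856  2.929  3.332  4.953  2.639  5.572  4.205  2.253  2.623  2.570  2.796  2.301  2.943  4.322  4.404  3.817
K  1.075  1.594  1.437  1.337  2.661  0.821  0.913  2.639  0.050  2.706  1.936  1.164  0.777  0.815  0.533  0.313  0.945  2.150  2.025  1.651
L  3.533  4.350  2.399  2.690  5.424  3.055  3.357  5.572  2.706  6.210  4.630  2.778  3.072  3.295  2.553  3.102  3.072  4.649  4.624  4.418
M  2.855  3.429  2.026  2.012  4.686  2.529  2.598  4.205  1.936  4.630  4.719  1.867  2.489  2.417  2.271  2.536  2.118  3.869  4.026  3.604
N  1.526  1.962  1.249  1.155  2.414  1.452  1.495  2.253  1.164  2.778  1.867  1.559  1.123  1.343  1.625  1.203  1.447  2.309  2.378  2.121
P  1.619  2.457  0.990  0.728  3.070  1.425  1.928  2.623  0.777  3.072  2.489  1.123  1.295  1.360  0.860  1.349  1.316  2.315  2.811  2.417
Q  1.377  2.212  1.291  1.128  2.979  0.909  1.292  2.570  0.815  3.295  2.417  1.343  1.360  0.851  1.479  0.699  1.295  2.082  2.165  2.227
R  1.142  2.249  1.922  1.741  3.112  1.252  1.668  2.796  0.533  2.553  2.271  1.625  0.860  1.479  1.415  1.144  1.474  2.232  2.351  2.395
S  1.885  2.078  1.408  1.263  2.703  1.416  1.117  2.301  0.313  3.102  2.536  1.203  1.349  0.699  1.144  1.459  1.272  2.338  2.153  2.306
T  1.966  2.525  1.185  1.168  3.515  1.467  2.138  2.943  0.945  3.072  2.118  1.447  1.316  1.295  1.474  1.272  1.623  2.582  2.303  2.267
V  3.105  3.980  1.800  1.944  4.768  2.278  2.878  4.322  2.150  4.649  3.869  2.309  2.315  2.082  2.232  2.338  2.582  4.124  4.105  3.603
W  3.112  3.875  2.276  2.272  4.565  2.595  2.833  4.404  2.025  4.624  4.026  2.378  2.811  2.165  2.351  2.153  2.303  4.105  4.155  3.502
Y  2.359  3.052  2.213  1.906  4.305  2.291  2.460  3.817  1.651  4.418  3.604  2.121  2.417  2.227  2.395  2.306  2.267  3.603  3.502  3.634
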