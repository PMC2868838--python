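# Miyazawa-Jernigan (1996) residue-residue contact energies e_ij,
# stored as magnitudes (|e_ij|, RT units) for use as intra-chain spring weights.
       A      C      D      E      F      G      H      I      K      L      M      N      P      Q      R      S      T      V      W      Y
A  2.720  3.570  1.700  1.510  4.810  2.310  2.410  4.580  1.310  4.910  3.940  1.840  2.030  1.890  1.830  2.010  2.320  4.040  3.820  3.360
C  3.570  5.440  2.410  2.270  5.800  3.160  3.600  5.500  1.950  5.830  4.990  2.590  3.070  2.850  2.570  2.860  3.110  4.960  4.950  4.160
D  1.700  2.410  1.210  1.020  3.480  1.590  2.320  3.170  1.680  3.400  2.570  1.680  1.330  1.460  2.290  1.630  1.800  2.480  2.840  2.760
E  1.510  2.270  1.020  0.910  3.560  1.220  2.150  3.270  1.800  3.590  2.890  1.510  1.260  1.420  2.270  1.480  1.740  2.670  2.990  2.790
F  4.810  5.800  3.480  3.560  7.260  4.130  4.770  6.840  3.360  7.280  6.560  3.750  4.250  4.100  3.980  4.020  4.280  6.290  6.160  5.660
G  2.310  3.160  1.590  1.220  4.130  2.240  2.150  3.780  1.150  4.160  3.390  1.740  1.870  1.660  1.720  1.820  2.080  3.380  3.420  3.010
H  2.410  3.600  2.320  2.150  4.770  2.150  3.050  4.140  1.350  4.540  3.980  2.080  2.250  1.980  2.160  2.110  2.420  3.580  3.980  3.520
I  4.580  5.500  3.170  3.270  6.840  3.780  4.140  6.540  3.010  7.040  6.020  3.240  3.760  3.670  3.630  3.520  4.030  6.050  5.780  5.250
K  1.310  1.950  1.680  1.800  3.360  1.150  1.350  3.010  0.120  3.370  2.480  1.210  0.970  1.290  0.590  1.050  1.310  2.490  2.690  2.600
L  4.910  5.830  3.400  3.590  7.280  4.160  4.540  7.040  3.370  7.370  6.410  3.740  4.200  4.040  4.030  3.920  4.340  6.480  6.140  5.670
M  3.940  4.990  2.570  2.890  6.560  3.390  3.980  6.020  2.480  6.410  5.460  2.950  3.450  3.300  3.120  3.030  3.510  5.320  5.550  4.910
N  1.840  2.590  1.680  1.510  3.750  1.740  2.080  3.240  1.210  3.740  2.950  1.680  1.530  1.710  1.640  1.580  1.880  2.830  3.070  2.760
P  2.030  3.070  1.330  1.260  4.250  1.870  2.250  3.760  0.970  4.200  3.450  1.530  1.750  1.730  1.700  1.570  1.900  3.320  3.730  3.190
Q  1.890  2.850  1.460  1.420  4.100  1.660  1.980  3.670  1.290  4.040  3.300  1.710  1.730  1.540  1.800  1.490  1.900  3.070  3.110  2.970
R  1.830  2.570  2.290  2.270  3.980  1.720  2.160  3.630  0.590  4.030  3.120  1.640  1.700  1.800  1.550  1.620  1.900  3.070  3.410  3.160
S  2.010  2.860  1.630  1.480  4.020  1.820  2.110  3.520  1.050  3.920  3.030  1.580  1.570  1.490  1.620  1.670  1.960  3.050  2.990  2.780
T  2.320  3.110  1.800  1.740  4.280  2.080  2.420  4.030  1.310  4.340  3.510  1.880  1.900  1.900  1.900  1.960  2.120  3.460  3.220  3.010
V  4.040  4.960  2.480  2.670  6.290  3.380  3.580  6.050  2.490  6.480  5.320  2.830  3.320  3.070  3.070  3.050  3.460  5.520  5.180  4.620
W  3.820  4.950  2.840  2.990  6.160  3.420  3.980  5.780  2.690  6.140  5.550  3.070  3.730  3.110  3.410  2.990  3.220  5.180  5.060  4.660
Y  3.360  4.160  2.760  2.790  5.660  3.010  3.520  5.250  2.600  5.670  4.910  2.760  3.190  2.970  3.160  2.780  3.010  4.620  4.660  4.170
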