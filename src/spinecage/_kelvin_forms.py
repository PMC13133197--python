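"""Frozen closed-form stiffness entries of the stretched Kelvin lattice.

Derived symbolically by energy minimization of the periodic 24-strut
tetrakaidecahedron frame (Euler-Bernoulli beams, rigid joints), with the
periodic corrections reduced to their exact symmetry orbits.  The cell has
unit in-plane period, height R, strut inclination tan(theta) = R; section
properties A, I, J refer to the circular strut cross-section, E0/G0 to the
solid.  Entries are Voigt: C11 (transverse), C33 (rise), C12, C13, C44
(out-of-plane shear), C66 (in-plane shear), in units of stress of E0.
"""

from math import sqrt


def tetragonal_stiffness_entries(R, E0, G0, A, I, J):
    """Return (C11, C33, C12, C13, C44, C66) for aspect ratio R >= 1."""
    x0 = sqrt(2)
    x1 = A*x0
    x2 = 192*I
    x3 = x1*x2
    x4 = A**2
    x5 = 2*x4
    x6 = x0*x5
    x7 = R**2
    x8 = R**4
    x9 = R**6
    x10 = x1*x9
    x11 = x4*x7
    x12 = x4*x8
    x13 = x4*x9
    x14 = 3*x13
    x15 = I**2
    x16 = x15*x7
    x17 = 36864*x16
    x18 = x0*x17
    x19 = sqrt(x7 + 1)
    x20 = A*x19
    x21 = x2*x20
    x22 = x19*x4
    x23 = R**8
    x24 = x22*x23
    x25 = I*x7
    x26 = x20*x25
    x27 = x11*x19
    x28 = 3*x8
    x29 = 384*I
    x30 = A*x29
    x31 = 768*I
    x32 = A*x31
    x33 = x1*x7
    x34 = x19*x33
    x35 = I*x34
    x36 = x0*x27
    x37 = 1/R
    x38 = A*E0
    x39 = 4*x38
    x40 = x37*x39
    x41 = 2*x20
    x42 = x29*x7
    x43 = x19*x42
    x44 = I*x0
    x45 = 192*x19
    x46 = x1*x8
    x47 = x19*x46
    x48 = R*x39
    x49 = A**3
    x50 = x0*x49
    x51 = 8*x50
    x52 = x4*x44
    x53 = x50*x7
    x54 = R**10
    x55 = x50*x54
    x56 = 6*x50
    x57 = I**3
    x58 = 14155776*x57
    x59 = x58*x8
    x60 = x0*x59
    x61 = x19*x49
    x62 = 147456*x16
    x63 = 147456*x15
    x64 = 73728*x15
    x65 = x22*x31
    x66 = 64*x61
    x67 = x15*x8
    x68 = x20*x9
    x69 = I*x8
    x70 = x13*x19
    x71 = 1/(2304*I*x24 + 5376*I*x27 + 3072*I*x70 + R**14*x50 + R**12*x56 + x1*x23*x64 + x1*x62 + x10*x64 + 3264*x11*x44 + 7680*x12*x44 + 8064*x13*x44 + x20*x62 + 589824*x20*x67 + 6144*x22*x69 + 30*x23*x50 + 3264*x23*x52 + 36*x23*x61 + x46*x63 + 60*x50*x8 + 53*x50*x9 + x51 + 192*x52*x54 + 576*x52 + 35*x53 + 8*x54*x61 + x54*x65 + 15*x55 + x60 + 40*x61*x7 + 12*x61 + x63*x68 + x65 + x66*x8 + x66*x9)
    x72 = A*x15
    x73 = 73728*x72
    x74 = I*x11
    x75 = I*x12
    x76 = x0*x29
    x77 = x1*x19
    x78 = x16*x77
    x79 = 36864*x15
    x80 = 4*x49
    x81 = x29*x4
    x82 = x0*x19
    x83 = x80*x82
    x84 = x19*x9
    x85 = x19*x8
    x86 = 9*x19*x53 + x19*x55 + 6*x23*x49 + x23*x83 + x29*x36 + 18*x49*x7 + 30*x49*x8 + 22*x49*x9 + x51*x85 + x56*x84 + x80 - x81 + x83
    x87 = x13*x29
    x88 = x22*x44
    x89 = 2*I
    x90 = E0*x89
    x91 = G0*J
    x92 = x90*x91
    x93 = 384*E0
    x94 = x15*x93
    x95 = x91*x94
    x96 = E0*x91
    x97 = I*x96
    x98 = 16*x46
    x99 = x0*x7
    x100 = E0**2
    x101 = x100*x57
    x102 = 384*x101
    x103 = 768*x101
    x104 = x0*x8
    x105 = x16*x96
    x106 = x100*x15
    x107 = x106*x20
    x108 = G0**2*J**2
    x109 = x108*x20
    x110 = x108*x7
    x111 = x108*x2
    x112 = 1152*x19
    x113 = 2*x8
    x114 = x106*x7
    x115 = E0*x44
    x116 = x38*x89
    x117 = 6*x38
    x118 = 4*E0
    x119 = x19*x90
    cC11 = x40*(x11 + x13 + x17 + x18*x19 + x19*x3 + x19*x6 + x30*x9 + x30 + x32*x7 + x32*x8 + 576*x35 + 2*x36 + x5*x8)/(7*x0*x11 + 8*x0*x12 + x0*x14 + x10*x2 + x14*x19 + x18 + x21*x8 + x21 + x22*x28 + 4*x22 + x24 + 1152*x26 + 5*x27 + x3*x7 + x3*x8 + x3 + x6)
    cC33 = x48*(x29 + x34 + x42 + x44*x45 + x47)/(x1*x28 + x1 + x10 + 3*x33 + x41*x7 + x41 + x43)
    cC12 = x40*x71*(x10*x19*x79 + x13*x31 - x19*x60 - x22*x76 + x23*x31*x4 - x23*x73 - x24*x76 - 1152*x44*x70 + x47*x64 + x59 - 294912*x72*x8 - 368640*x72*x9 - 1536*x74 - 1152*x75 - 110592*x78 + x86)
    cC13 = x48*x71*(x23*x81 - 192*x24*x44 - x47*x79 - x58*x7 - x73*x9 - x73 - 1920*x74 - 2304*x75 - x77*x79 - 221184*x78 + 768*x8*x88 - x82*x87 + x86 - x87 - 576*x88)
    cC44 = 1536*I*R*x38*(x106*x113 + x106 + x108 + x110 + x113*x97 + 2*x114*x82 + 3*x114 + 2*x115*x19*x91 + 4*x25*x96 + x92)/(x0*x102*x9 + 768*x0*x105 + x0*x95 + 2*x1*x110 + x1*x92 + 12*x10*x106 + 4*x10*x97 + x101*x45 + 960*x101*x85 + x102*x84 + x102*x99 + x103*x104 + x103*x19*x7 + x104*x95 + x105*x112 + 4*x106*x33 + x106*x98 + 7*x107*x7 + 19*x107*x8 + 5*x107*x9 + x107 + x108*x43 + 2*x108*x46 + x109*x8 + x109 + x110*x41 + x111*x19 + x111*x85 + x112*x67*x96 + x19*x95 + 12*x20*x69*x96 + 17*x26*x96 + 14*x33*x97 + x41*x97 + 5*x68*x97 + x84*x95 + x97*x98)
    cC66 = E0*x32*x37*(x115 + x119*x7 + x119 + x91*x99)/(I*x118*x77 + x116*x9 + x116 + x117*x25 + x117*x69 + x118*x35 + x16*x82*x93 + x34*x91 + x42*x91 + x47*x91 + x82*x94 + x94)
    return (cC11, cC33, cC12, cC13, cC44, cC66)
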