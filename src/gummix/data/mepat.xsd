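<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="floatList">
    <xs:list itemType="xs:double"/>
  </xs:simpleType>

  <xs:simpleType name="intList">
    <xs:list itemType="xs:integer"/>
  </xs:simpleType>

  <xs:simpleType name="tokenList">
    <xs:list itemType="xs:token"/>
  </xs:simpleType>

  <xs:complexType name="matrixType">
    <xs:simpleContent>
      <xs:extension base="floatList">
        <xs:attribute name="rows" type="xs:positiveInteger" use="required"/>
        <xs:attribute name="cols" type="xs:positiveInteger" use="required"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:element name="mepat">
    <xs:complexType>
      <xs:sequence>

        <xs:element name="test_food">
          <xs:complexType>
            <xs:simpleContent>
              <xs:extension base="xs:string">
                <xs:attribute name="brand" type="xs:string" use="required"/>
                <xs:attribute name="colour_pair" type="xs:string" use="required"/>
                <xs:attribute name="dimensions_mm" type="xs:string" use="required"/>
              </xs:extension>
            </xs:simpleContent>
          </xs:complexType>
        </xs:element>

        <xs:element name="experimental_settings">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="cycles" type="intList"/>
              <xs:element name="segmentation">
                <xs:complexType>
                  <xs:attribute name="spatial_bandwidth" type="xs:double" use="required"/>
                  <xs:attribute name="range_bandwidth" type="xs:double" use="required"/>
                  <xs:attribute name="ms_iterations" type="xs:positiveInteger" use="required"/>
                  <xs:attribute name="n_init" type="xs:positiveInteger" use="required"/>
                  <xs:attribute name="distance_weight" type="xs:double" use="required"/>
                  <xs:attribute name="min_colour_separation" type="xs:double" use="required"/>
                  <xs:attribute name="closing_radius" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="convex_hull" type="xs:boolean" use="required"/>
                  <xs:attribute name="seed" type="xs:integer" use="required"/>
                  <xs:attribute name="variant" type="xs:token" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="scanner_dpi" type="xs:positiveInteger" use="required"/>
            <xs:attribute name="flattening_thickness_mm" type="xs:double" use="required"/>
          </xs:complexType>
        </xs:element>

        <xs:element name="characterizers">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="feature" minOccurs="1" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="code" type="xs:token" use="required"/>
                  <xs:attribute name="q" type="xs:double" use="required"/>
                  <xs:attribute name="rho" type="xs:double" use="required"/>
                  <xs:attribute name="gamma" type="xs:nonNegativeInteger" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="n_bins" type="xs:positiveInteger" use="required"/>
          </xs:complexType>
        </xs:element>

        <xs:element name="classifier">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="stage" minOccurs="1" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="features" type="tokenList"/>
                    <xs:element name="scaler_mean" type="floatList"/>
                    <xs:element name="scaler_scale" type="floatList"/>
                    <xs:element name="w1" type="matrixType"/>
                    <xs:element name="b1" type="floatList"/>
                    <xs:element name="w2" type="matrixType"/>
                    <xs:element name="b2" type="floatList"/>
                  </xs:sequence>
                  <xs:attribute name="target_t" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="h" type="xs:positiveInteger" use="required"/>
                  <xs:attribute name="mcc_sg" type="xs:double" use="required"/>
                  <xs:attribute name="seed" type="xs:integer" use="required"/>
                  <xs:attribute name="epochs" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="threshold" type="xs:double" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>

        <xs:element name="operator">
          <xs:complexType>
            <xs:attribute name="name" type="xs:string" use="required"/>
            <xs:attribute name="institution" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>

        <xs:element name="performance">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="global">
                <xs:complexType>
                  <xs:attribute name="mcc" type="xs:double"/>
                  <xs:attribute name="sensitivity" type="xs:double"/>
                  <xs:attribute name="specificity" type="xs:double"/>
                  <xs:attribute name="accuracy" type="xs:double"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="stage_mcc" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:double">
                      <xs:attribute name="t" type="xs:nonNegativeInteger" use="required"/>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="unclassified" type="xs:nonNegativeInteger" use="required"/>
          </xs:complexType>
        </xs:element>

      </xs:sequence>
      <xs:attribute name="uid" use="required">
        <xs:simpleType>
          <xs:restriction base="xs:token">
            <xs:pattern value="[0-9a-fA-F]{8}-[0-9a-fA-F]{4}-[0-9a-fA-F]{4}-[0-9a-fA-F]{4}-[0-9a-fA-F]{12}"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
      <xs:attribute name="created" type="xs:string" use="required"/>
      <xs:attribute name="uploaded" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
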