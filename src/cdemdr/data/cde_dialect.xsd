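<?xml version="1.0" encoding="UTF-8"?>
<!-- Normative documentation of the artifact's CDE-registry and
     data-dictionary XML dialect.  The dialect is artifact-defined; it models
     the structure of an ISO 11179-style registry export (one record per
     data element with object class, property, value domain, permissible
     values, concept codes and workflow status) and of a data dictionary
     grouping variables into clinical study domains, but makes no claim of
     bit-compatibility with any production export schema. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:element name="CDERegistry">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="DataElement" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="DataElement">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="PublicId" type="xs:string"/>
        <xs:element name="Version" type="xs:string"/>
        <xs:element name="LongName" type="xs:string"/>
        <xs:element name="PreferredName" type="xs:string" minOccurs="0"/>
        <xs:element name="Definition" type="xs:string" minOccurs="0"/>
        <xs:element name="WorkflowStatus" type="xs:string"/>
        <xs:element ref="ObjectClass"/>
        <xs:element ref="Property"/>
        <xs:element ref="ValueDomain"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:complexType name="ComponentType">
    <xs:sequence>
      <xs:element name="Name" type="xs:string"/>
      <xs:element name="PublicId" type="xs:string" minOccurs="0"/>
      <xs:element ref="ConceptCode" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:element name="ObjectClass" type="ComponentType"/>
  <xs:element name="Property" type="ComponentType"/>

  <xs:element name="ValueDomain">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Name" type="xs:string"/>
        <xs:element name="PublicId" type="xs:string" minOccurs="0"/>
        <xs:element name="Datatype" type="xs:string"/>
        <xs:element ref="PermissibleValue" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="PermissibleValue">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Value" type="xs:string"/>
        <xs:element name="Meaning" type="xs:string" minOccurs="0"/>
        <xs:element ref="ConceptCode" minOccurs="0"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <!-- Post-coordinated codes are colon-joined atoms, e.g. "C25431:C25275" -->
  <xs:element name="ConceptCode">
    <xs:complexType>
      <xs:simpleContent>
        <xs:extension base="xs:string">
          <xs:attribute name="source" type="xs:string" default="NCIt"/>
        </xs:extension>
      </xs:simpleContent>
    </xs:complexType>
  </xs:element>

  <xs:element name="DataDictionary">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Domain" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="Variable" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Name" type="xs:string"/>
                    <xs:element name="CDERef" type="xs:string" minOccurs="0"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="name" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

</xs:schema>
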